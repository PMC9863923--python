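"""Synthetic leaf-clip reflectance spectra with deficiency structure.

The generator emulates the statistical structure the analysis pipeline
assumes: a latent chlorosis level c ∈ [0, 1] per leaf drives a smooth
parametric reflectance curve — visible floor plus a green peak near
550 nm whose amplitude rises with chlorophyll loss, a red-reflectance
lift, a logistic red edge whose centre shifts to shorter wavelengths as
c grows, an NIR plateau, and a SWIR decline with Gaussian water-
absorption dips near 1450 and 1940 nm.  The curve is calibrated so that
reflectance at 550 nm is exactly 12.6% for healthy tissue (c = 0) and
41.1% for severe chlorosis (c = 1), and a severely chlorotic leaf
reflects more than a healthy one at every wavelength from 350 to
1000 nm.

Treatments differ in their chlorosis distribution, red-edge response
and the fraction of visually asymptomatic leaves (which grows with
plant maturity for P and K): N shows strong uniform chlorosis; S is
similar but with a smaller red-edge shift and tighter severity spread;
Mg is moderate with high within-leaf variability; K is mild with many
asymptomatic mature leaves; P is bimodal — asymptomatic or strongly
spotted.  A transparent closed-form curve is used instead of a physical
radiative-transfer model so every calibration anchor is directly
testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bandselect import GapSegParams, gap_segment_derivative
from .io import (
    Maturity,
    SampleMeta,
    SpectraSet,
    Treatment,
    WavelengthGrid,
    default_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LeafModelParams",
    "DeficiencyEffect",
    "ScenarioConfig",
    "DEFAULT_EFFECTS",
    "SEVERITY_THRESHOLDS",
    "reflectance_model",
    "red_edge_position",
    "simulate_dataset",
    "default_scenario",
]

#: Latent-chlorosis cut points mapping c to the 4-level severity rating
#: (none / low / intermediate / high).
SEVERITY_THRESHOLDS = (0.1, 0.4, 0.7)


@dataclass(frozen=True)
class LeafModelParams:
    """Parameters of the closed-form leaf reflectance curve (percent units).

    ``green_peak_control`` and ``green_peak_severe`` are exact anchors:
    the green-peak amplitude is solved so the modelled reflectance at
    ``green_center_nm`` equals them at c = 0 and c = 1 respectively.
    """

    nir_plateau: float = 47.0
    green_peak_control: float = 12.6
    green_peak_severe: float = 41.1
    green_center_nm: float = 550.0
    green_width_nm: float = 45.0
    red_edge_center_control_nm: float = 712.0
    red_edge_shift_severe_nm: float = -18.0
    red_edge_width_nm: float = 14.0
    vis_floor: float = 6.0
    red_lift_center_nm: float = 645.0
    red_lift_width_nm: float = 45.0
    red_lift_severe: float = 6.0
    vis_lift_severe: float = 1.5
    nir_lift_severe: float = 2.0
    swir_base: float = 22.0
    swir_decline_center_nm: float = 1650.0
    swir_decline_width_nm: float = 180.0
    water_dip_1450: float = 10.0
    water_dip_1940: float = 14.0
    water_dip_width_1450_nm: float = 40.0
    water_dip_width_1940_nm: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.green_peak_control < self.green_peak_severe < 100:
            raise ValueError("need 0 < green_peak_control < green_peak_severe < 100")
        if self.red_edge_shift_severe_nm >= 0:
            raise ValueError("red_edge_shift_severe_nm must be negative (shift to shorter wavelengths)")
        for name in ("nir_plateau", "vis_floor", "swir_base"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name}={v} outside (0, 100)")


@dataclass(frozen=True)
class DeficiencyEffect:
    """How one treatment maps onto the latent chlorosis model.

    ``asymptomatic_fraction`` (per maturity stage) is the probability a
    sampled leaf looks control-like regardless of treatment;
    ``extra_variance_multiplier`` inflates the smooth within-leaf noise
    for nonuniform symptoms; ``red_edge_shift_scale`` scales the
    severe-chlorosis red-edge shift (1 = full shift).
    """

    treatment: Treatment
    chlorosis_mean: float
    chlorosis_sd: float
    asymptomatic_fraction: dict = field(default_factory=dict)
    extra_variance_multiplier: float = 1.0
    red_edge_shift_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chlorosis_mean <= 1.0:
            raise ValueError("chlorosis_mean must be in [0, 1]")
        for stage, frac in self.asymptomatic_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"asymptomatic_fraction[{stage}]={frac} outside [0, 1]")

    def asymptomatic(self, maturity: Maturity) -> float:
        return float(self.asymptomatic_fraction.get(Maturity(maturity), 0.0))


def _stage_fractions(young: float, intermediate: float, mature: float) -> dict:
    return {
        Maturity.YOUNG: young,
        Maturity.INTERMEDIATE: intermediate,
        Maturity.MATURE: mature,
    }


#: Default treatment effects, encoding the qualitative symptom structure:
#: N strong uniform chlorosis; S similar but smaller red-edge shift and
#: tighter spread; Mg moderate with high within-leaf variance; K mild
#: with many asymptomatic mature leaves; P bimodal with extra variance.
DEFAULT_EFFECTS: dict[Treatment, DeficiencyEffect] = {
    Treatment.CONTROL: DeficiencyEffect(
        Treatment.CONTROL, chlorosis_mean=0.02, chlorosis_sd=0.02,
    ),
    Treatment.N_DEF: DeficiencyEffect(
        Treatment.N_DEF, chlorosis_mean=0.80, chlorosis_sd=0.06,
        asymptomatic_fraction=_stage_fractions(0.0, 0.05, 0.05),
    ),
    Treatment.S_DEF: DeficiencyEffect(
        Treatment.S_DEF, chlorosis_mean=0.60, chlorosis_sd=0.05,
        asymptomatic_fraction=_stage_fractions(0.0, 0.05, 0.10),
        red_edge_shift_scale=0.35,
    ),
    Treatment.MG_DEF: DeficiencyEffect(
        Treatment.MG_DEF, chlorosis_mean=0.50, chlorosis_sd=0.12,
        asymptomatic_fraction=_stage_fractions(0.05, 0.10, 0.15),
        extra_variance_multiplier=2.0, red_edge_shift_scale=0.9,
    ),
    Treatment.K_DEF: DeficiencyEffect(
        Treatment.K_DEF, chlorosis_mean=0.25, chlorosis_sd=0.10,
        asymptomatic_fraction=_stage_fractions(0.10, 0.25, 0.50),
        red_edge_shift_scale=0.8,
    ),
    Treatment.P_DEF: DeficiencyEffect(
        Treatment.P_DEF, chlorosis_mean=0.40, chlorosis_sd=0.05,
        asymptomatic_fraction=_stage_fractions(0.05, 0.25, 0.35),
        extra_variance_multiplier=1.4,
    ),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """A simulated measurement campaign at one growth stage."""

    classes: tuple[Treatment, ...]
    n_per_class: int
    maturity: Maturity
    seed: int
    grid: WavelengthGrid = field(default_factory=default_grid)
    noise_sd_white: float = 0.5
    noise_sd_correlated: float = 1.0
    noise_correlation_length_nm: float = 50.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(Treatment(c) for c in self.classes))
        object.__setattr__(self, "maturity", Maturity(self.maturity))
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _components(wl: np.ndarray, c: float, p: LeafModelParams):
    """Edge blend L, visible curve without green amplitude, NIR/SWIR curve, green shape."""
    edge_centre = p.red_edge_center_control_nm + c * p.red_edge_shift_severe_nm
    l_edge = _logistic((wl - edge_centre) / p.red_edge_width_nm)
    green = np.exp(-0.5 * ((wl - p.green_center_nm) / p.green_width_nm) ** 2)
    red = np.exp(-0.5 * ((wl - p.red_lift_center_nm) / p.red_lift_width_nm) ** 2)
    vis_base = p.vis_floor + c * p.vis_lift_severe + c * p.red_lift_severe * red
    decline = _logistic((wl - p.swir_decline_center_nm) / p.swir_decline_width_nm)
    dips = p.water_dip_1450 * np.exp(
        -0.5 * ((wl - 1450.0) / p.water_dip_width_1450_nm) ** 2
    ) + p.water_dip_1940 * np.exp(-0.5 * ((wl - 1940.0) / p.water_dip_width_1940_nm) ** 2)
    nir = (
        p.nir_plateau
        + c * p.nir_lift_severe
        - (p.nir_plateau - p.swir_base) * decline
        - dips
    )
    return l_edge, vis_base, nir, green


def _green_amplitude_anchor(c_anchor: float, target: float, p: LeafModelParams) -> float:
    """Solve the green-peak amplitude so R(green_center, c_anchor) == target."""
    wl = np.array([p.green_center_nm])
    l_edge, vis_base, nir, green = _components(wl, c_anchor, p)
    l0, v0, n0, g0 = float(l_edge[0]), float(vis_base[0]), float(nir[0]), float(green[0])
    # target = (v0 + A*g0) * (1 - l0) + n0 * l0   =>   solve for A
    return (target - n0 * l0 - v0 * (1.0 - l0)) / (g0 * (1.0 - l0))


def reflectance_model(
    wavelengths_nm, c: float, p: LeafModelParams = LeafModelParams()
) -> np.ndarray:
    """Deterministic percent reflectance at chlorosis level c ∈ [0, 1].

    The visible curve and the NIR/SWIR curve are blended by the red-edge
    logistic; the green-peak amplitude interpolates linearly in c
    between values solved exactly from the control and severe anchors.
    Output clipped to [0, 100].
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"chlorosis c={c} outside [0, 1]")
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    a0 = _green_amplitude_anchor(0.0, p.green_peak_control, p)
    a1 = _green_amplitude_anchor(1.0, p.green_peak_severe, p)
    amp = a0 + c * (a1 - a0)
    l_edge, vis_base, nir, green = _components(wl, c, p)
    r = (vis_base + amp * green) * (1.0 - l_edge) + nir * l_edge
    return np.clip(r, 0.0, 100.0)


def red_edge_position(
    spectrum, grid: WavelengthGrid, params: GapSegParams = GapSegParams(order=1)
) -> float:
    """Wavelength of the maximum first derivative within 660–760 nm.

    The derivative is the gap-segment filter at its defaults.  Raises
    when the grid does not cover the window or the derivative is flat
    there (no red edge to locate).
    """
    wl = grid.wavelengths_nm
    if wl.min() > 660.0 or wl.max() < 760.0:
        raise ValueError("grid must cover 660-760 nm to locate the red edge")
    deriv = gap_segment_derivative(spectrum, grid, params)
    window = (wl >= 660.0) & (wl <= 760.0) & np.isfinite(deriv)
    if not window.any():
        raise ValueError("no valid derivative values in the 660-760 nm window")
    d = deriv[window]
    if float(d.max() - d.min()) < 1e-9:
        raise ValueError("derivative is flat in 660-760 nm; red edge undefined")
    return float(wl[window][int(np.argmax(d))])


def _severity_from_chlorosis(c: float) -> int:
    t1, t2, t3 = SEVERITY_THRESHOLDS
    return 1 + (c >= t1) + (c >= t2) + (c >= t3)


def _correlated_noise(rng: np.random.Generator, n_bands: int, sigma_bands: float,
                      target_sd: float) -> np.ndarray:
    white = rng.standard_normal(n_bands)
    smooth = gaussian_filter1d(white, sigma=sigma_bands, mode="reflect")
    # rescale analytically: filtering an impulse gives the kernel, whose
    # l2 norm is the sd shrink factor for white-noise input
    impulse = np.zeros(min(n_bands, int(8 * sigma_bands) + 1) * 2 + 1)
    impulse[impulse.size // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma=sigma_bands, mode="constant")
    shrink = float(np.sqrt((kernel**2).sum()))
    return smooth * (target_sd / shrink)


def simulate_dataset(
    sc: ScenarioConfig,
    effects: dict[Treatment, DeficiencyEffect] | None = None,
    p: LeafModelParams = LeafModelParams(),
) -> SpectraSet:
    """Generate a :class:`SpectraSet` for one scenario; reproducible by seed.

    Per sample: draw a chlorosis level from its treatment's distribution
    (forced control-like with the maturity-dependent asymptomatic
    probability), evaluate the reflectance curve, add smooth correlated
    noise plus white noise, clip to [0, 100], and derive the severity
    rating from the latent chlorosis.
    """
    effects = effects if effects is not None else DEFAULT_EFFECTS
    for cls in sc.classes:
        if cls not in effects:
            raise ValueError(f"no deficiency effect defined for class {cls.value!r}")
    rng = np.random.default_rng(sc.seed)
    wl = sc.grid.wavelengths_nm
    n_bands = wl.size
    sigma_bands = sc.noise_correlation_length_nm / sc.grid.spacing_nm

    leaf_ranges = {
        Maturity.YOUNG: (1, 7),
        Maturity.INTERMEDIATE: (7, 13),
        Maturity.MATURE: (13, 19),
    }
    lo_leaf, hi_leaf = leaf_ranges[sc.maturity]

    spectra = np.empty((len(sc.classes) * sc.n_per_class, n_bands))
    meta: list[SampleMeta] = []
    i = 0
    for cls in sc.classes:
        eff = effects[cls]
        p_eff = replace(
            p,
            red_edge_shift_severe_nm=p.red_edge_shift_severe_nm * eff.red_edge_shift_scale,
        ) if eff.red_edge_shift_scale != 1.0 else p
        asympt_p = eff.asymptomatic(sc.maturity)
        for _ in range(sc.n_per_class):
            if rng.random() < asympt_p:
                c = float(np.clip(abs(rng.normal(0.02, 0.02)), 0.0, 1.0))
            else:
                c = float(np.clip(rng.normal(eff.chlorosis_mean, eff.chlorosis_sd), 0.0, 1.0))
            base = reflectance_model(wl, c, p_eff)
            noise = rng.normal(0.0, sc.noise_sd_white, n_bands)
            if sc.noise_sd_correlated > 0:
                noise = noise + _correlated_noise(
                    rng, n_bands, sigma_bands,
                    sc.noise_sd_correlated * eff.extra_variance_multiplier,
                )
            spectra[i] = np.clip(base + noise, 0.0, 100.0)
            meta.append(
                SampleMeta(
                    sample_id=f"{cls.value}-{sc.maturity.value}-{i:04d}",
                    treatment=cls,
                    maturity=sc.maturity,
                    severity=_severity_from_chlorosis(c),
                    leaf_index=int(rng.integers(lo_leaf, hi_leaf)),
                    replicate=int(rng.integers(1, 5)),
                    trial=int(rng.integers(1, 3)),
                )
            )
            i += 1
    provenance = {
        "generator": "specdx.synthdata.simulate_dataset",
        "seed": int(sc.seed),
        "maturity": sc.maturity.value,
        "classes": [c.value for c in sc.classes],
        "n_per_class": int(sc.n_per_class),
        "grid_nm": [float(wl[0]), float(wl[-1]), float(sc.grid.spacing_nm)],
        "units": "percent reflectance",
    }
    return SpectraSet(grid=sc.grid, reflectance=spectra, meta=meta, provenance=provenance)


#: Classes measured per growth stage: young plants were compared for
#: control/N/P/S only; intermediate and mature stages cover all six.
STAGE_CLASSES: dict[Maturity, tuple[Treatment, ...]] = {
    Maturity.YOUNG: (
        Treatment.CONTROL, Treatment.N_DEF, Treatment.P_DEF, Treatment.S_DEF,
    ),
    Maturity.INTERMEDIATE: tuple(Treatment),
    Maturity.MATURE: tuple(Treatment),
}


def default_scenario(
    stage: Maturity | str, n_per_class: int = 40, seed: int = 0, **overrides
) -> ScenarioConfig:
    """The default scenario for one growth stage (classes per stage above)."""
    stage = Maturity(stage)
    return ScenarioConfig(
        classes=STAGE_CLASSES[stage],
        n_per_class=n_per_class,
        maturity=stage,
        seed=seed,
        **overrides,
    )
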