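"""Band selection: per-band information scoring, smoothing, peak extraction.

The discriminative value of each wavelength is scored either by Shannon
entropy of the band's discretised reflectance values (class-free: how
much variability the band carries) or by information gain (class-aware:
how much knowing the band's discretised value reduces uncertainty about
the treatment label).  Score curves are smoothed with a Savitzky–Golay
filter; spectral derivatives are computed and smoothed in one pass with
the gap-segment (Norris) filter.  Peaks — strict local maxima within a
sliding span, with plateaus aggregated to their central wavelength —
are ranked by score and the top k reported.

Both scorers are provided because the class-free and class-aware
readings of "information entropy" are common in the hyperspectral
band-selection literature; the pipeline default is information gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import SpectraSet, WavelengthGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SGParams",
    "GapSegParams",
    "ScoreProfile",
    "SelectedBand",
    "shannon_entropy",
    "information_gain",
    "entropy_profile",
    "savitzky_golay",
    "smooth_profile",
    "gap_segment_derivative",
    "detect_peaks",
    "top_k",
    "select_bands",
    "METHODS",
]

METHODS = ("entropy", "infogain", "d1", "d2")


@dataclass(frozen=True)
class SGParams:
    """Savitzky–Golay smoothing parameters.

    ``window`` must be odd and exceed ``poly_order`` by at least 2; an
    even window is bumped up to the next odd value with a logged notice
    (a symmetric SG filter cannot use an even window).
    """

    poly_order: int = 3
    window: int = 11

    def __post_init__(self) -> None:
        w = self.window
        if w % 2 == 0:
            logger.info("SG window %d is even; using closest valid odd window %d", w, w + 1)
            object.__setattr__(self, "window", w + 1)
            w += 1
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if w < self.poly_order + 2:
            raise ValueError(
                f"window {w} too small for poly_order {self.poly_order} "
                f"(need odd window >= poly_order + 2)"
            )


@dataclass(frozen=True)
class GapSegParams:
    """Gap-segment derivative parameters.

    The filter averages over segments of ``segment`` bands separated
    from the evaluation point by ``gap`` bands; total filter length is
    ``2*segment + 2*gap + 1`` (default 3/2 → length 11).  The second
    derivative needs an odd segment so the centre segment is symmetric
    about the evaluation point.
    """

    order: int = 1
    segment: int = 3
    gap: int = 2

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if self.segment < 1 or self.gap < 0:
            raise ValueError("segment must be >= 1 and gap >= 0")
        if self.order == 2 and self.segment % 2 == 0:
            raise ValueError("second-order gap-segment derivative requires an odd segment")

    @property
    def filter_length(self) -> int:
        return 2 * (self.segment + self.gap) + 1

    @property
    def half_length(self) -> int:
        return self.segment + self.gap


@dataclass
class ScoreProfile:
    """Per-band importance scores on a wavelength grid.

    ``scores`` may contain NaN at positions a filter marked invalid
    (e.g. gap-segment edges); peak search skips them.
    """

    grid: WavelengthGrid
    scores: np.ndarray
    method: str
    smoothed: bool = False

    def __post_init__(self) -> None:
        sc = np.asarray(self.scores, dtype=float)
        if sc.shape != (len(self.grid),):
            raise ValueError("scores length must equal grid length")
        self.scores = sc


@dataclass(frozen=True)
class SelectedBand:
    """A chosen wavelength with its score, selection method, and rank."""

    wavelength_nm: float
    score: float
    method: str
    rank: int = 0


def shannon_entropy(values, n_bins: int = 10) -> float:
    """Shannon entropy (bits) of values discretised into equal-width bins.

    Bins span [min, max] of the values themselves; a degenerate
    all-equal input occupies a single bin and has zero entropy.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("shannon_entropy requires at least 2 values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / v.size
    return float(-(p * np.log2(p)).sum())


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return np.zeros(values.size, dtype=int)
    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _label_entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(values, labels, n_bins: int = 10) -> float:
    """Mutual information (bits) between discretised values and class labels.

    IG = H(labels) − Σ_b p(b) · H(labels | bin b).  Zero when a single
    class is present or the values carry no class information.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.size != y.size:
        raise ValueError(f"length mismatch: {v.size} values vs {y.size} labels")
    if v.size == 0:
        raise ValueError("information_gain requires non-empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.unique(y).size < 2:
        return 0.0
    h_y = _label_entropy(y)
    bins = _bin_indices(v, n_bins)
    ig = h_y
    for b in np.unique(bins):
        mask = bins == b
        ig -= mask.mean() * _label_entropy(y[mask])
    return float(max(ig, 0.0))


def entropy_profile(s: SpectraSet, method: str = "infogain", n_bins: int = 10) -> ScoreProfile:
    """Score every band independently by entropy or information gain."""
    if s.n_samples < 2:
        raise ValueError("entropy_profile requires at least 2 samples")
    if method not in ("entropy", "infogain"):
        raise ValueError(f"method must be 'entropy' or 'infogain', got {method!r}")
    if method == "entropy":
        scores = np.array(
            [shannon_entropy(s.reflectance[:, j], n_bins) for j in range(s.n_bands)]
        )
    else:
        y = s.labels()
        if np.unique(y).size < 2:
            raise ValueError("information gain requires at least 2 classes")
        scores = np.array(
            [information_gain(s.reflectance[:, j], y, n_bins) for j in range(s.n_bands)]
        )
    return ScoreProfile(grid=s.grid, scores=scores, method=method, smoothed=False)


def _sg_weights(window: int, poly_order: int) -> np.ndarray:
    """Central convolution weights: value at the window centre of the LSQ polynomial."""
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    a = np.vander(x, poly_order + 1, increasing=True)
    # value at x=0 is the constant coefficient of the LSQ fit
    return np.linalg.pinv(a)[0]


def savitzky_golay(y, params: SGParams = SGParams()) -> np.ndarray:
    """Savitzky–Golay smoothing with one-sided truncated windows at the edges.

    Interior points are replaced by the centre value of the local
    least-squares polynomial; each edge point is the fit of the same
    polynomial on its truncated window evaluated at that point, so the
    output has the same length as the input.  Exactly reproduces
    polynomials of degree <= ``poly_order``.
    """
    v = np.asarray(y, dtype=float)
    n = v.size
    if n < params.window:
        raise ValueError(f"input length {n} shorter than window {params.window}")
    half = params.window // 2
    out = np.empty(n)
    w = _sg_weights(params.window, params.poly_order)
    out[half : n - half] = np.convolve(v, w[::-1], mode="valid")
    for i in range(half):
        for idx, lo, hi in ((i, 0, i + half + 1), (n - 1 - i, n - i - half - 1, n)):
            x = np.arange(lo, hi, dtype=float) - idx
            coeffs = np.polynomial.polynomial.polyfit(x, v[lo:hi], params.poly_order)
            out[idx] = coeffs[0]
    return out


def smooth_profile(profile: ScoreProfile, params: SGParams = SGParams()) -> ScoreProfile:
    """SG-smooth a score profile, skipping leading/trailing NaN runs."""
    sc = profile.scores
    finite = np.isfinite(sc)
    out = np.full(sc.shape, np.nan)
    if finite.any():
        lo = int(np.argmax(finite))
        hi = int(sc.size - np.argmax(finite[::-1]))
        out[lo:hi] = savitzky_golay(sc[lo:hi], params)
    return replace_scores(profile, out, smoothed=True)


def replace_scores(profile: ScoreProfile, scores: np.ndarray, smoothed: bool) -> ScoreProfile:
    return ScoreProfile(grid=profile.grid, scores=scores, method=profile.method, smoothed=smoothed)


def gap_segment_derivative(
    spectrum, grid: WavelengthGrid, params: GapSegParams = GapSegParams()
) -> np.ndarray:
    """Gap-segment (Norris) spectral derivative: segment means, then finite differences.

    Order 1: difference of the mean over a segment on each side of the
    point (offset by the gap), divided by the centre-to-centre distance
    in nm — exact for linear input.  Order 2: second difference of the
    left/centre/right segment means divided by the squared distance —
    exact for quadratic input.  Positions within half the filter length
    of either end are returned as NaN and excluded from peak search.
    """
    v = np.asarray(spectrum, dtype=float)
    n = v.size
    if n != len(grid):
        raise ValueError("spectrum length must equal grid length")
    if n < params.filter_length:
        raise ValueError(
            f"spectrum length {n} shorter than filter length {params.filter_length}"
        )
    d_lambda = grid.spacing_nm  # raises on non-uniform grids
    m, g = params.segment, params.gap
    half = params.half_length
    # seg_sum[j] = sum of v[j : j + m]
    seg_mean = np.convolve(v, np.ones(m), mode="valid") / m
    out = np.full(n, np.nan)
    i = np.arange(half, n - half)
    right = seg_mean[i + g + 1]
    left = seg_mean[i - g - m]
    if params.order == 1:
        dist_nm = (2 * g + m + 1) * d_lambda  # centre-to-centre of the two segments
        out[i] = (right - left) / dist_nm
    else:
        centre = seg_mean[i - (m - 1) // 2]
        d_nm = (g + (m + 1) // 2) * d_lambda  # adjacent segment-centre spacing
        out[i] = (left + right - 2.0 * centre) / d_nm**2
    return out


def detect_peaks(
    profile: ScoreProfile, span: int = 10, use_absolute: bool = False
) -> list[SelectedBand]:
    """Strict local maxima of a (smoothed) score profile within ±span bands.

    A band is a peak when its score (absolute value when
    ``use_absolute``) is the maximum over the surrounding span and a
    strictly smaller score exists on each side within the span — so a
    monotone profile yields no peaks.  Maximal runs of consecutive
    equal-score candidates (plateaus) are aggregated and reported at
    their central wavelength (lower median for even runs).  Results are
    sorted by score descending.
    """
    if span < 2:
        raise ValueError("span must be >= 2")
    s = np.abs(profile.scores) if use_absolute else profile.scores.copy()
    n = s.size
    valid = np.isfinite(s)
    candidates = []
    for i in np.flatnonzero(valid):
        lo, hi = max(0, i - span), min(n, i + span + 1)
        left = s[lo:i][valid[lo:i]]
        right = s[i + 1 : hi][valid[i + 1 : hi]]
        neighbours = np.concatenate([left, right])
        si = s[i]
        if neighbours.size and np.any(neighbours > si):
            continue
        if not (left.size and np.any(left < si)):
            continue
        if not (right.size and np.any(right < si)):
            continue
        candidates.append(i)

    peaks: list[SelectedBand] = []
    run: list[int] = []
    for i in candidates + [None]:  # sentinel flushes the last run
        if run and (i is None or i != run[-1] + 1 or s[i] != s[run[-1]]):
            centre = run[(len(run) - 1) // 2]
            peaks.append(
                SelectedBand(
                    wavelength_nm=float(profile.grid.wavelengths_nm[centre]),
                    score=float(s[centre]),
                    method=profile.method,
                )
            )
            run = []
        if i is not None:
            run.append(i)
    peaks.sort(key=lambda b: (-b.score, b.wavelength_nm))
    return peaks


def top_k(bands: list[SelectedBand], k: int = 5) -> list[SelectedBand]:
    """The k highest-score bands, re-ranked 1..k; ties go to the lower wavelength."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(bands, key=lambda b: (-b.score, b.wavelength_nm))
    if len(ordered) < k:
        logger.info("only %d peaks available for top_k(k=%d)", len(ordered), k)
    return [replace(b, rank=r + 1) for r, b in enumerate(ordered[:k])]


def _uniform_blocks(grid: WavelengthGrid) -> list[slice]:
    """Maximal contiguous runs of uniform spacing (a band mask splits the grid)."""
    wl = grid.wavelengths_nm
    if wl.size < 2:
        return [slice(0, wl.size)]
    d = np.diff(wl)
    step = np.min(d)
    breaks = np.flatnonzero(~np.isclose(d, step, rtol=0, atol=1e-9)) + 1
    edges = [0, *breaks.tolist(), wl.size]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _blockwise_gap_segment(spectrum: np.ndarray, grid: WavelengthGrid,
                           params: GapSegParams) -> np.ndarray:
    """Gap-segment derivative applied within each uniformly spaced grid block."""
    out = np.full(len(grid), np.nan)
    for blk in _uniform_blocks(grid):
        if blk.stop - blk.start >= params.filter_length:
            out[blk] = gap_segment_derivative(
                spectrum[blk], WavelengthGrid(grid.wavelengths_nm[blk]), params
            )
    return out


def _derivative_contrast_profile(
    s: SpectraSet, params: GapSegParams, contrast: str = "pooled"
) -> ScoreProfile:
    """Score bands by the class-mean spectral derivative.

    Class-mean spectra are differentiated with the gap-segment filter
    (per contiguous uniform grid block, so a water-band mask is
    tolerated).  ``contrast='pooled'`` (default) scores each band by the
    absolute derivative of the balanced mean of the class means — peaks
    mark where reflectance changes fastest (the red edge, the green-peak
    flanks), the locations a selection from plotted derivative curves
    picks out.  ``contrast='std'`` scores by the cross-class standard
    deviation of the derivative, highlighting where class slopes
    diverge.
    """
    if contrast not in ("pooled", "std"):
        raise ValueError(f"contrast must be 'pooled' or 'std', got {contrast!r}")
    y = s.labels()
    classes = sorted(set(y), key=lambda t: t.value)
    if len(classes) < 2:
        raise ValueError("derivative-based selection requires at least 2 classes")
    derivs = np.vstack(
        [
            _blockwise_gap_segment(
                s.reflectance[np.fromiter((yi == c for yi in y), bool, count=len(y))].mean(axis=0),
                s.grid,
                params,
            )
            for c in classes
        ]
    )
    if contrast == "pooled":
        scores = np.abs(derivs.mean(axis=0))
    else:
        scores = np.std(derivs, axis=0, ddof=1)
    return ScoreProfile(
        grid=s.grid, scores=scores, method=f"d{params.order}", smoothed=True
    )


def select_bands(
    s: SpectraSet,
    method: str = "infogain",
    n_bins: int = 10,
    sg: SGParams = SGParams(),
    gapseg: GapSegParams | None = None,
    span: int = 10,
    k: int = 5,
    contrast: str = "pooled",
) -> pd.DataFrame:
    """Full band-selection pass: score → smooth → peak-find → top-k.

    Entropy/information-gain profiles are SG-smoothed before peak
    search; derivative methods score bands by the cross-class spread of
    the gap-segment derivative of the class-mean spectra (the filter is
    itself a smoother, so no further smoothing is applied).  The result
    is a deterministic table with columns method, rank, wavelength_nm,
    score.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method in ("entropy", "infogain"):
        profile = smooth_profile(entropy_profile(s, method, n_bins), sg)
        use_absolute = False
    else:
        order = 1 if method == "d1" else 2
        params = gapseg if gapseg is not None else GapSegParams(order=order)
        if params.order != order:
            params = replace(params, order=order)
        profile = _derivative_contrast_profile(s, params, contrast)
        use_absolute = True
    bands = top_k(detect_peaks(profile, span=span, use_absolute=use_absolute), k)
    return pd.DataFrame(
        {
            "method": [b.method for b in bands],
            "rank": [b.rank for b in bands],
            "wavelength_nm": [b.wavelength_nm for b in bands],
            "score": [b.score for b in bands],
        }
    )
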