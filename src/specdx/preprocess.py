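"""Data-preparation rules applied before band selection and classification.

Three operations: exclusion of the SWIR water-absorption bands
(1355–1450 nm and 1800–1950 nm by default, endpoints inclusive),
row subsetting by maturity stage / treatment / minimum symptom severity,
and a percent-scale normalisation utility for fraction-scale inputs.
Missing bands are never imputed — masking is explicit, so derivative
filters always see a contiguous uniform grid or fail loudly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import (
    Maturity,
    SpectraSet,
    SpectraValidationError,
    Treatment,
    WavelengthGrid,
    replace_reflectance,
)

logger = logging.getLogger(__name__)

__all__ = ["BandMask", "WATER_BANDS", "apply_band_mask", "subset", "to_percent"]


@dataclass(frozen=True)
class BandMask:
    """Closed wavelength intervals [lo, hi] (nm) to exclude from analysis.

    Intervals are normalised on construction: sorted and merged when
    overlapping, so membership tests are order-independent.
    """

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Iterable[Sequence[float]]):
        cleaned = []
        for pair in intervals:
            lo, hi = float(pair[0]), float(pair[1])
            if lo > hi:
                raise ValueError(f"mask interval [{lo:g}, {hi:g}] has lo > hi")
            cleaned.append((lo, hi))
        cleaned.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in cleaned:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        object.__setattr__(self, "intervals", tuple(merged))

    def contains(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Boolean array: True where a wavelength falls inside any interval."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        inside = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.intervals:
            inside |= (wl >= lo) & (wl <= hi)
        return inside


#: Default water-absorption exclusion mask (SWIR), endpoints inclusive.
WATER_BANDS = BandMask([(1355.0, 1450.0), (1800.0, 1950.0)])


def apply_band_mask(s: SpectraSet, mask: BandMask = WATER_BANDS) -> SpectraSet:
    """Drop every band whose wavelength falls inside the mask.

    Sample count is unchanged and surviving columns are copied verbatim.
    Raises if the mask would remove every band.
    """
    inside = mask.contains(s.grid.wavelengths_nm)
    keep = ~inside
    if not keep.any():
        raise SpectraValidationError("band mask removes all bands")
    return replace_reflectance(
        s,
        reflectance=s.reflectance[:, keep],
        grid=WavelengthGrid(s.grid.wavelengths_nm[keep]),
    )


def subset(
    s: SpectraSet,
    maturity: Maturity | str | None = None,
    treatments: Iterable[Treatment | str] | None = None,
    min_severity: int | None = None,
) -> SpectraSet:
    """Rows satisfying all supplied predicates, input order preserved.

    At least one filter must be supplied.  An empty result is legal;
    downstream operations guard against it.
    """
    if maturity is None and treatments is None and min_severity is None:
        raise ValueError("subset requires at least one filter")
    keep = np.ones(s.n_samples, dtype=bool)
    if maturity is not None:
        m = Maturity(maturity)
        keep &= np.array([meta.maturity == m for meta in s.meta])
    if treatments is not None:
        wanted = {Treatment(t) for t in treatments}
        keep &= np.array([meta.treatment in wanted for meta in s.meta])
    if min_severity is not None:
        keep &= np.array([meta.severity >= min_severity for meta in s.meta])
    idx = np.flatnonzero(keep)
    return replace_reflectance(
        s,
        reflectance=s.reflectance[idx, :],
        meta=[s.meta[i] for i in idx],
    )


def to_percent(s: SpectraSet, assume_fraction: bool = False) -> SpectraSet:
    """Normalise reflectance to the percent (0–100) convention.

    With ``assume_fraction`` the values (required to lie in [0, 1]) are
    multiplied by 100; otherwise the set is returned unchanged, with a
    warning logged when the data look fraction-scaled (max <= 1).
    Idempotent on percent-scale data.
    """
    if assume_fraction:
        if s.n_samples and float(np.nanmax(s.reflectance)) > 1.0:
            raise SpectraValidationError(
                "assume_fraction=True but reflectance values exceed 1"
            )
        return replace_reflectance(s, reflectance=s.reflectance * 100.0)
    if s.n_samples and s.reflectance.size and float(np.nanmax(s.reflectance)) <= 1.0:
        logger.warning(
            "reflectance maximum is <= 1; data may be fraction-scaled "
            "(pass assume_fraction=True to convert)"
        )
    return s
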