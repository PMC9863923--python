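"""Spectral data model and plain-text I/O.

A :class:`SpectraSet` is the pipeline's universal currency: a samples ×
bands matrix of percent reflectance on an explicit wavelength grid, with
one :class:`SampleMeta` record per spectrum (treatment, maturity stage,
symptom-severity rating, replicate structure).

On disk the canonical layout is a wide CSV — the metadata columns
followed by one column per wavelength, named by its value in nanometres —
which is self-describing and diff-able.  A long (tidy) layout of
``(sample_id, wavelength_nm, reflectance)`` triples with a metadata
sidecar is also supported.  Dataset-level provenance (instrument range,
units, generation seed for synthetic sets) travels in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Treatment",
    "Maturity",
    "SampleMeta",
    "WavelengthGrid",
    "SpectraSet",
    "SpectraValidationError",
    "default_grid",
    "assign_maturity",
    "read_spectra",
    "write_spectra",
    "METADATA_COLUMNS",
]


class SpectraValidationError(ValueError):
    """Raised when spectra or metadata violate the data-model contract."""


class Treatment(str, Enum):
    """Nutrient treatment: full-nutrition control or single-macronutrient omission."""

    CONTROL = "control"
    N_DEF = "N_def"
    P_DEF = "P_def"
    K_DEF = "K_def"
    MG_DEF = "Mg_def"
    S_DEF = "S_def"


class Maturity(str, Enum):
    """Plant growth stage, assigned from expanded-leaf count (see :func:`assign_maturity`)."""

    YOUNG = "young"
    INTERMEDIATE = "intermediate"
    MATURE = "mature"


#: Symptom-severity rating scale: 1 none, 2 low, 3 intermediate, 4 high.
SEVERITY_LEVELS = (1, 2, 3, 4)

METADATA_COLUMNS = [
    "sample_id",
    "treatment",
    "maturity",
    "severity",
    "leaf_index",
    "replicate",
    "trial",
]


@dataclass(frozen=True)
class SampleMeta:
    """Per-spectrum metadata record."""

    sample_id: str
    treatment: Treatment
    maturity: Maturity
    severity: int
    leaf_index: int = 1
    replicate: int = 1
    trial: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        object.__setattr__(self, "maturity", Maturity(self.maturity))
        if self.severity not in SEVERITY_LEVELS:
            raise SpectraValidationError(
                f"sample {self.sample_id!r}: severity {self.severity} not in {SEVERITY_LEVELS}"
            )
        for name in ("leaf_index", "replicate", "trial"):
            if getattr(self, name) < 1:
                raise SpectraValidationError(
                    f"sample {self.sample_id!r}: {name} must be >= 1"
                )


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraValidationError("wavelength grid must be a non-empty 1-D sequence")
        if np.any(wl <= 0):
            raise SpectraValidationError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise SpectraValidationError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def spacing_nm(self) -> float:
        """Uniform grid spacing in nm; raises if the grid is not uniform."""
        d = np.diff(self.wavelengths_nm)
        if d.size == 0:
            raise SpectraValidationError("grid has a single band; spacing undefined")
        if not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise SpectraValidationError("grid spacing is not uniform")
        return float(d[0])

    def is_uniform(self) -> bool:
        d = np.diff(self.wavelengths_nm)
        return d.size > 0 and bool(np.allclose(d, d[0], rtol=0, atol=1e-9))


def default_grid() -> WavelengthGrid:
    """The instrument's nominal 1-nm analysis grid, 350..2500 nm inclusive (2151 bands)."""
    return WavelengthGrid(np.arange(350.0, 2501.0, 1.0))


@dataclass
class SpectraSet:
    """Samples × bands percent-reflectance matrix with aligned metadata.

    Invariants enforced on construction: reflectance finite and within
    [0, 100]; one metadata record per spectrum; one column per grid
    wavelength.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    meta: list[SampleMeta]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 2:
            raise SpectraValidationError("reflectance must be 2-D (samples x bands)")
        self.reflectance = r
        self.meta = list(self.meta)
        if r.shape[0] != len(self.meta):
            raise SpectraValidationError(
                f"{r.shape[0]} spectra but {len(self.meta)} metadata records"
            )
        if r.shape[1] != len(self.grid):
            raise SpectraValidationError(
                f"{r.shape[1]} reflectance columns but grid has {len(self.grid)} bands"
            )
        bad = ~np.isfinite(r) | (r < 0) | (r > 100)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise SpectraValidationError(
                f"reflectance {r[i, j]!r} out of [0, 100] at sample "
                f"{self.meta[i].sample_id!r}, wavelength {self.grid.wavelengths_nm[j]:g} nm"
            )

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def labels(self) -> np.ndarray:
        """Treatment label per sample, as an object array of :class:`Treatment`."""
        return np.array([m.treatment for m in self.meta], dtype=object)

    def meta_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": m.sample_id,
                "treatment": m.treatment.value,
                "maturity": m.maturity.value,
                "severity": m.severity,
                "leaf_index": m.leaf_index,
                "replicate": m.replicate,
                "trial": m.trial,
            }
            for m in self.meta
        ]
        return pd.DataFrame(rows, columns=METADATA_COLUMNS)

    def equals(self, other: "SpectraSet", atol: float = 1e-6) -> bool:
        return (
            np.allclose(self.grid.wavelengths_nm, other.grid.wavelengths_nm, atol=atol)
            and self.reflectance.shape == other.reflectance.shape
            and np.allclose(self.reflectance, other.reflectance, atol=atol)
            and self.meta == other.meta
        )


def assign_maturity(leaf_count: int) -> Maturity:
    """Growth stage from the number of expanded leaves.

    Young plants have 6 or fewer leaves, intermediate plants 7 to 12,
    and mature plants more than 12.
    """
    if leaf_count < 1:
        raise ValueError(f"leaf_count must be >= 1, got {leaf_count}")
    if leaf_count <= 6:
        return Maturity.YOUNG
    if leaf_count <= 12:
        return Maturity.INTERMEDIATE
    return Maturity.MATURE


def _wavelength_label(wl: float) -> str:
    return f"{wl:g}"


def _meta_from_frame(df: pd.DataFrame, source: str) -> list[SampleMeta]:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraValidationError(f"{source}: missing metadata columns {missing}")
    meta = []
    for _, row in df.iterrows():
        try:
            meta.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]),
                    treatment=Treatment(row["treatment"]),
                    maturity=Maturity(row["maturity"]),
                    severity=int(row["severity"]),
                    leaf_index=int(row["leaf_index"]),
                    replicate=int(row["replicate"]),
                    trial=int(row["trial"]),
                )
            )
        except ValueError as exc:
            raise SpectraValidationError(
                f"{source}: invalid metadata for sample {row['sample_id']!r}: {exc}"
            ) from exc
    return meta


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    """(metadata sidecar, provenance sidecar) for a long-layout file."""
    return path.with_suffix(".meta.csv"), path.with_suffix(".json")


def read_spectra(path: str | Path, layout: str = "wide") -> SpectraSet:
    """Read a :class:`SpectraSet` from a wide or long CSV.

    Wide layout: one row per sample, metadata columns then one column per
    wavelength (named by its nm value).  Long layout: ``(sample_id,
    wavelength_nm, reflectance)`` triples plus a ``<stem>.meta.csv``
    metadata sidecar.  Wavelengths are sorted ascending on read, so a
    permuted long file round-trips to the same set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "wide":
        df = pd.read_csv(path)
        meta = _meta_from_frame(df[[c for c in df.columns if c in METADATA_COLUMNS]], str(path))
        band_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
        try:
            wls = np.array([float(c) for c in band_cols])
        except ValueError as exc:
            raise SpectraValidationError(
                f"{path}: non-numeric wavelength column name: {exc}"
            ) from exc
        order = np.argsort(wls)
        grid = WavelengthGrid(wls[order])
        values = df[band_cols].to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            for col in band_cols:
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise SpectraValidationError(
                        f"{path}: non-numeric reflectance {df[col].iloc[i]!r} at sample "
                        f"{df['sample_id'].iloc[i]!r}, wavelength {col} nm"
                    )
            raise SpectraValidationError(f"{path}: non-numeric reflectance values")
        refl = values[:, order].astype(float)
    elif layout == "long":
        df = pd.read_csv(path)
        for col in ("sample_id", "wavelength_nm", "reflectance"):
            if col not in df.columns:
                raise SpectraValidationError(f"{path}: long layout requires column {col!r}")
        meta_path, _ = _sidecar_paths(path)
        if not meta_path.exists():
            raise SpectraValidationError(f"{path}: metadata sidecar {meta_path} not found")
        meta = _meta_from_frame(pd.read_csv(meta_path), str(meta_path))
        dup = df.duplicated(subset=["sample_id", "wavelength_nm"])
        if dup.any():
            row = df[dup].iloc[0]
            raise SpectraValidationError(
                f"{path}: duplicate (sample, wavelength) pair "
                f"({row['sample_id']!r}, {row['wavelength_nm']:g} nm)"
            )
        wide = df.pivot(index="sample_id", columns="wavelength_nm", values="reflectance")
        wide = wide.sort_index(axis=1)
        ids = [m.sample_id for m in meta]
        missing = set(wide.index) - set(ids)
        if missing:
            raise SpectraValidationError(
                f"{path}: samples without metadata: {sorted(missing)}"
            )
        if wide.isna().to_numpy().any():
            raise SpectraValidationError(f"{path}: missing (sample, wavelength) triples")
        grid = WavelengthGrid(wide.columns.to_numpy(dtype=float))
        refl = wide.loc[ids].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")

    provenance = None
    prov_path = path.with_suffix(".json")
    if prov_path.exists():
        provenance = json.loads(prov_path.read_text())
    return SpectraSet(grid=grid, reflectance=refl, meta=meta, provenance=provenance)


def write_spectra(s: SpectraSet, path: str | Path, layout: str = "wide") -> Path:
    """Write a :class:`SpectraSet`; round-trips through :func:`read_spectra`.

    Values are serialized with 8 significant digits.  Provenance, when
    present, goes to a ``<stem>.json`` sidecar; long layout additionally
    writes a ``<stem>.meta.csv`` metadata sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if layout == "wide":
        bands = pd.DataFrame(
            s.reflectance,
            columns=[_wavelength_label(wl) for wl in s.grid.wavelengths_nm],
        )
        df = pd.concat([s.meta_frame(), bands], axis=1)
        df.to_csv(path, index=False, float_format="%.8g")
    elif layout == "long":
        ids = np.repeat([m.sample_id for m in s.meta], s.n_bands)
        wls = np.tile(s.grid.wavelengths_nm, s.n_samples)
        long = pd.DataFrame(
            {"sample_id": ids, "wavelength_nm": wls, "reflectance": s.reflectance.ravel()}
        )
        long.to_csv(path, index=False, float_format="%.8g")
        meta_path, _ = _sidecar_paths(path)
        s.meta_frame().to_csv(meta_path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")
    if s.provenance is not None:
        path.with_suffix(".json").write_text(json.dumps(s.provenance, indent=2))
    return path


def replace_reflectance(
    s: SpectraSet,
    reflectance: np.ndarray,
    grid: WavelengthGrid | None = None,
    meta: Sequence[SampleMeta] | None = None,
) -> SpectraSet:
    """Functional update helper used by the preprocessing steps."""
    return SpectraSet(
        grid=grid if grid is not None else s.grid,
        reflectance=reflectance,
        meta=list(meta) if meta is not None else s.meta,
        provenance=s.provenance,
    )
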