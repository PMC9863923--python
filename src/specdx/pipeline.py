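"""End-to-end orchestration: simulate → preprocess → select bands → classify.

A :class:`PipelineConfig` captures every knob — analysis wavelength
range, water-band mask, band-selection method and its parameters, PC
count, fold count, seed, and CV scope — in a single YAML-serialisable
record, so a run is reproducible from its config file and seed alone.
Choices the method description leaves open (entropy vs information
gain, fold-safe vs fit-then-validate PCA, the SG window) all surface as
explicit config keys.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bandselect, classify, preprocess, synthdata
from .io import Maturity, SpectraSet, Treatment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run; unknown keys rejected."""

    seed: int = 0
    analysis_range_nm: tuple[float, float] = (350.0, 2500.0)
    mask_intervals_nm: tuple[tuple[float, float], ...] = ((1355.0, 1450.0), (1800.0, 1950.0))
    method: str = "infogain"
    n_bins: int = 10
    sg_window: int = 11
    sg_poly_order: int = 3
    segment: int = 3
    gap: int = 2
    span: int = 10
    top_k: int = 5
    n_components: int = 10
    folds: int = 5
    scope: str = "fold_safe"
    regularization: float = 0.0
    scenario: dict | None = None  # {"stage": ..., "n_per_class": ...} to simulate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_range_nm" in raw:
            raw["analysis_range_nm"] = tuple(raw["analysis_range_nm"])
        if "mask_intervals_nm" in raw:
            raw["mask_intervals_nm"] = tuple(tuple(p) for p in raw["mask_intervals_nm"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["analysis_range_nm"] = list(self.analysis_range_nm)
        d["mask_intervals_nm"] = [list(p) for p in self.mask_intervals_nm]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineReport:
    """In-memory result bundle of one pipeline run."""

    selected_bands: pd.DataFrame
    cv_result: classify.CVResult
    accuracy_table: pd.DataFrame
    dimensionality_reduction_percent: float
    n_bands_analyzed: int
    applied_defaults: dict


def _accuracy_table(cv: classify.CVResult) -> pd.DataFrame:
    rows = [
        {"class": getattr(c, "value", c), "accuracy_percent": acc, "n_test": int(n)}
        for (c, acc), n in zip(
            cv.per_class_accuracy.items(), cv.confusion.counts.sum(axis=1), strict=True
        )
    ]
    rows.append(
        {
            "class": "overall",
            "accuracy_percent": cv.overall_accuracy,
            "n_test": int(cv.confusion.counts.sum()),
        }
    )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    spectra: SpectraSet | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full pipeline; optionally write report tables to ``out_dir``.

    With no input spectra a scenario must be configured, in which case
    the dataset is simulated first.  Outputs: selected-bands table,
    confusion matrix, per-class/overall accuracy table, a dimensionality
    summary and a log of every default applied.
    """
    applied: dict = {}
    if spectra is None:
        if config.scenario is None:
            raise ValueError("no input spectra and no scenario configured")
        scen = dict(config.scenario)
        stage = Maturity(scen.pop("stage"))
        sc = synthdata.default_scenario(stage, seed=config.seed, **scen)
        spectra = synthdata.simulate_dataset(sc)
        applied["simulated"] = {"stage": stage.value, "n_per_class": sc.n_per_class}

    lo, hi = config.analysis_range_nm
    wl = spectra.grid.wavelengths_nm
    outside = (wl < lo) | (wl > hi)
    if outside.any():
        from .io import WavelengthGrid, replace_reflectance

        keep = ~outside
        spectra = replace_reflectance(
            spectra, spectra.reflectance[:, keep], grid=WavelengthGrid(wl[keep])
        )
        applied["analysis_range_nm"] = [lo, hi]
    mask = preprocess.BandMask(config.mask_intervals_nm)
    n_before = spectra.n_bands
    spectra = preprocess.apply_band_mask(spectra, mask)
    applied["water_band_mask"] = {
        "intervals_nm": [list(p) for p in mask.intervals],
        "bands_removed": n_before - spectra.n_bands,
    }

    sg = bandselect.SGParams(poly_order=config.sg_poly_order, window=config.sg_window)
    if sg.window != config.sg_window:
        applied["sg_window"] = {"requested": config.sg_window, "used": sg.window}
    selected = bandselect.select_bands(
        spectra,
        method=config.method,
        n_bins=config.n_bins,
        sg=sg,
        gapseg=bandselect.GapSegParams(
            order=1 if config.method != "d2" else 2,
            segment=config.segment,
            gap=config.gap,
        ),
        span=config.span,
        k=config.top_k,
    )

    cv = classify.crossvalidate(
        spectra,
        k=config.folds,
        n_components=config.n_components,
        scope=config.scope,
        seed=config.seed,
        regularization=config.regularization,
    )
    table = _accuracy_table(cv)
    dim_red = classify.dimensionality_reduction_percent(
        spectra.n_bands, config.n_components
    )
    report = PipelineReport(
        selected_bands=selected,
        cv_result=cv,
        accuracy_table=table,
        dimensionality_reduction_percent=dim_red,
        n_bands_analyzed=spectra.n_bands,
        applied_defaults=applied,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        selected.to_csv(out / "selected_bands.csv", index=False, float_format="%.8g")
        cv.confusion.to_frame().to_csv(out / "confusion_matrix.csv")
        table.to_csv(out / "accuracy_table.csv", index=False, float_format="%.8g")
        summary = {
            "seed": config.seed,
            "method": config.method,
            "scope": config.scope,
            "n_bands_analyzed": report.n_bands_analyzed,
            "n_components": config.n_components,
            "dimensionality_reduction_percent": dim_red,
            "overall_accuracy_percent": cv.overall_accuracy,
            "applied_defaults": applied,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report
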