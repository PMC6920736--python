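"""End-to-end orchestration: extract -> stats -> classify, with manifests.

The pipeline reads a directory of per-subject RF containers plus one
reference-phantom container, builds the eight parametric maps per subject,
aggregates the 40-feature vector, screens group differences, and evaluates
the three LOOCV classifier protocols for 1-, 2- and 3-feature models.  A
run manifest (config, seed, package/numpy versions) accompanies every
feature table so any report can be regenerated from it.

All randomness used anywhere in a run flows from the single configured seed
through named substreams (:func:`stage_rng`), so stages rerun in isolation
reproduce their in-pipeline results.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import CLASSIFIER_KINDS, ClassifierResult, SubjectRecord, loocv_evaluate
from .cohort_stats import summarize_cohort
from .maps_texture import (
    FEATURE_NAMES,
    ExtractionConfig,
    aggregate_subject_features,
    build_parametric_maps,
)
from .rf_core import ROIMask, RFFrame, load_reference, load_rf_frame
import h5py

__all__ = ["PipelineConfig", "stage_rng", "run_extract", "run_stats", "run_classify", "run_all"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream of the single pipeline seed."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass
class PipelineConfig:
    """Run settings; geometry defaults follow the acquisition description."""

    window_mm: float = 2.0
    overlap_frac: float = 0.94
    Ng: int = 16
    distances: tuple[int, ...] = (1, 2, 3, 4)
    directions: tuple[int, ...] = (0, 45, 90, 135)
    ar_order: int = 10
    fft_pad: int = 4
    max_features: int = 3
    classifier: str = "logistic"
    seed: int = 0
    input_dir: str = ""
    out_dir: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.Ng < 2:
            raise ValueError("Ng must be >= 2")
        if self.classifier not in CLASSIFIER_KINDS:
            raise ValueError(f"classifier must be one of {CLASSIFIER_KINDS}")

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            window_mm=self.window_mm,
            overlap_frac=self.overlap_frac,
            fft_pad=self.fft_pad,
            Ng=self.Ng,
            distances=tuple(self.distances),
            directions=tuple(self.directions),
            ar_order=self.ar_order,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("distances", "directions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        d["directions"] = list(self.directions)
        return {
            "config": d,
            "seed": self.seed,
            "qusradiomics_version": __version__,
            "numpy_version": np.__version__,
        }


def _load_subject(path: Path) -> tuple[RFFrame, ROIMask, str]:
    frame = load_rf_frame(path)
    with h5py.File(path, "r") as fh:
        label = str(fh.attrs.get("label", ""))
        if "roi" not in fh or "mask" not in fh["roi"]:
            raise ValueError(f"{path} has no ROI mask")
        mask = np.asarray(fh["roi"]["mask"]) > 0
        subject_id = str(fh["roi"].attrs.get("subject_id", path.stem))
    roi = ROIMask(mask, subject_id=subject_id or path.stem)
    return frame, roi, label


def run_extract(config: PipelineConfig) -> pd.DataFrame:
    """Per-subject map building and feature aggregation.

    Reads ``<input_dir>/reference.h5`` and every other ``*.h5`` as a subject;
    writes ``features.csv`` and ``manifest.json`` under ``out_dir``.  A
    subject that fails is recorded in the manifest and skipped.
    """
    input_dir = Path(config.input_dir)
    ref_path = input_dir / "reference.h5"
    if not ref_path.exists():
        raise FileNotFoundError(f"missing reference phantom {ref_path}")
    subject_paths = sorted(p for p in input_dir.glob("*.h5") if p.name != "reference.h5")
    if not subject_paths:
        raise FileNotFoundError(f"no subject containers in {input_dir}")
    reference = load_reference(ref_path)
    extraction = config.extraction()

    rows = []
    failures = {}
    for path in subject_paths:
        try:
            frame, roi, label = _load_subject(path)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                maps = build_parametric_maps(frame, roi, reference, extraction)
                features = aggregate_subject_features(maps, extraction)
            rows.append({"subject_id": roi.subject_id, "label": label, **features})
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            failures[path.name] = repr(exc)
    if not rows:
        raise RuntimeError(f"all subjects failed: {failures}")
    table = pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv", index=False)
        manifest = config.to_manifest()
        manifest["n_subjects"] = len(rows)
        manifest["failures"] = failures
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failures:
        warnings.warn(f"{len(failures)} subject(s) failed extraction: {sorted(failures)}")
    return table


def records_from_table(table: pd.DataFrame) -> list[SubjectRecord]:
    from .maps_texture import FeatureVector

    records = []
    for _, row in table.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                features=FeatureVector({f: row[f] for f in FEATURE_NAMES}),
                label=str(row["label"]),
            )
        )
    return records


def run_stats(table: pd.DataFrame, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Group-difference screen; optionally writes ``stats.csv``."""
    comparisons = summarize_cohort(records_from_table(table), FEATURE_NAMES)
    stats = pd.DataFrame(
        [
            {
                "feature": c.feature,
                "mean_cr": c.mean_cr,
                "sd_cr": c.sd_cr,
                "mean_pr": c.mean_pr,
                "sd_pr": c.sd_pr,
                "test": c.test,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        stats.to_csv(Path(out_dir) / "stats.csv", index=False)
    return stats


def _result_dict(result: ClassifierResult) -> dict:
    m = result.metrics
    return {
        "classifier": result.kind,
        "max_features": result.max_features,
        "sensitivity_pct": round(m.sensitivity, 1),
        "specificity_pct": round(m.specificity, 1),
        "accuracy_pct": round(m.accuracy, 1),
        "auc": round(m.auc, 3),
        "auc_ci_95": [round(x, 3) for x in m.auc_ci],
        "selected_features": result.selected_feature_counts(),
    }


def run_classify(
    table: pd.DataFrame,
    classifier: str,
    max_features: int = 3,
    fixed_features: list[str] | None = None,
) -> ClassifierResult:
    records = records_from_table(table)
    return loocv_evaluate(
        records,
        classifier,
        max_features=max_features,
        feature_names=FEATURE_NAMES,
        fixed_features=fixed_features,
    )


def run_all(config: PipelineConfig) -> dict:
    """extract -> stats -> LOOCV for 1..max_features and all classifiers.

    Writes ``report.json`` and ``report.md`` under ``out_dir`` and returns
    the report dict.
    """
    table = run_extract(config)
    stats = run_stats(table, config.out_dir or None)
    report: dict = {
        "n_subjects": len(table),
        "n_features": len(FEATURE_NAMES),
        "stats_top": stats.head(10).to_dict(orient="records"),
        "models": [],
    }
    for kind in CLASSIFIER_KINDS:
        for k in range(1, config.max_features + 1):
            result = run_classify(table, kind, max_features=k)
            report["models"].append(_result_dict(result))
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.md").write_text(_report_markdown(report))
    return report


def _report_markdown(report: dict) -> str:
    lines = [
        "# QUS radiomics run report",
        "",
        f"Subjects: {report['n_subjects']}  Features: {report['n_features']}",
        "",
        "## Group differences (top features)",
        "",
        "| feature | mean CR | mean PR | test | p |",
        "|---|---|---|---|---|",
    ]
    for row in report["stats_top"]:
        lines.append(
            f"| {row['feature']} | {row['mean_cr']:.3g} | {row['mean_pr']:.3g} "
            f"| {row['test']} | {row['p_value']:.3g} |"
        )
    lines += [
        "",
        "## LOOCV classification",
        "",
        "| classifier | k | %Sn | %Sp | %Acc | AUC | 95% CI |",
        "|---|---|---|---|---|---|---|",
    ]
    for m in report["models"]:
        lo, hi = m["auc_ci_95"]
        lines.append(
            f"| {m['classifier']} | {m['max_features']} | {m['sensitivity_pct']} "
            f"| {m['specificity_pct']} | {m['accuracy_pct']} | {m['auc']} "
            f"| ({lo}, {hi}) |"
        )
    return "\n".join(lines) + "\n"
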