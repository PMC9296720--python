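"""End-to-end study replica: phantom cohort -> features -> selection -> model.

`run_full_pipeline` chains the stages with one master seed and writes a
self-describing run directory (resolved config, feature table, selection
report, model, confusion matrices and metrics), so a run can be
reproduced bit-for-bit from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from .imaging import RoiSpec
from .phantom import DENSITY_CLASSES, PhantomConfig, PhantomExam, generate_cohort, support_polygon
from .selection import SelectionReport, run_selection
from .texture import FEATURE_NAMES, TextureParams, extract_features

log = logging.getLogger("bct_texture")

__all__ = ["PipelineConfig", "PipelineResult", "phantom_roi", "extract_feature_table", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; fully JSON-serializable."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    margin_mm: float = 5.0
    texture: TextureParams = field(default_factory=TextureParams)
    n_per_class: int = 50
    train_frac: float = 0.7
    feature_set: str = "anova_pass"  # all | anova_pass | retained
    ridge: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.feature_set not in ("all", "anova_pass", "retained"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["gland_fraction_by_class"] = dict(d["phantom"]["gland_fraction_by_class"])
        d["phantom"]["slice_shape"] = list(d["phantom"]["slice_shape"])
        d["texture"]["directions"] = [list(v) for v in d["texture"]["directions"]]
        return d


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    selection: SelectionReport
    model: clf.MultinomialModel
    features_used: list[str]
    train_metrics: clf.ClassificationMetrics
    test_metrics: clf.ClassificationMetrics
    test_confusion: clf.ConfusionMatrix


def phantom_roi(config: PhantomConfig, margin_mm: float = 5.0) -> RoiSpec:
    """ROI for a phantom exam: the breast-support outline plus skin margin."""
    return RoiSpec(polygon=support_polygon(config), margin_mm=margin_mm)


def extract_feature_table(
    exams: Sequence[PhantomExam],
    params: TextureParams | None = None,
    margin_mm: float = 5.0,
) -> pd.DataFrame:
    """One row of 19 features per examination, with id and density label."""
    params = params or TextureParams()
    rows = []
    roi_cache: dict[tuple, RoiSpec] = {}
    for exam in exams:
        key = (exam.stack.slice_shape, exam.stack.pixel_spacing_mm)
        if key not in roi_cache:
            cfg = PhantomConfig(
                n_slices=exam.stack.n_slices,
                slice_shape=exam.stack.slice_shape,
                pixel_spacing_mm=exam.stack.pixel_spacing_mm,
            )
            roi_cache[key] = phantom_roi(cfg, margin_mm=margin_mm)
        feats = extract_features(exam.stack, roi_cache[key], params)
        rows.append({"exam_id": exam.exam_id, "density": exam.density_label, **feats})
    return pd.DataFrame(rows, columns=["exam_id", "density", *FEATURE_NAMES])


def run_full_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Generate a cohort, extract features, select, fit and evaluate."""
    t0 = time.time()
    log.info("generating cohort: %d exams, seed %d", 4 * config.n_per_class, config.seed)
    exams = generate_cohort(config.phantom, config.n_per_class, config.seed)
    log.info("extracting %d-feature table (%.1f s elapsed)", len(FEATURE_NAMES), time.time() - t0)
    table = extract_feature_table(exams, config.texture, margin_mm=config.margin_mm)

    log.info("running feature selection (%.1f s elapsed)", time.time() - t0)
    selection = run_selection(table)
    if config.feature_set == "all":
        features = list(FEATURE_NAMES)
    elif config.feature_set == "anova_pass":
        features = selection.candidates or list(FEATURE_NAMES)
    else:
        features = selection.retained or selection.candidates or list(FEATURE_NAMES)

    log.info("fitting multinomial model on %d features (%.1f s elapsed)", len(features), time.time() - t0)
    train, test = clf.split_stratified(table, config.train_frac, seed=config.seed)
    model = clf.fit_multinomial_lr(train, features, seed=config.seed, ridge=config.ridge)
    cm_train = clf.confusion_matrix(train["density"], clf.predict(model, train))
    cm_test = clf.confusion_matrix(test["density"], clf.predict(model, test))
    result = PipelineResult(
        feature_table=table,
        selection=selection,
        model=model,
        features_used=features,
        train_metrics=clf.classification_metrics(cm_train),
        test_metrics=clf.classification_metrics(cm_test),
        test_confusion=cm_test,
    )
    log.info(
        "done in %.1f s: train acc %.1f%%, test acc %.1f%%",
        time.time() - t0,
        result.train_metrics.overall_percent,
        result.test_metrics.overall_percent,
    )
    if out_dir is not None:
        _write_outputs(config, result, Path(out_dir))
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    result.feature_table.to_csv(out_dir / "features.csv", index=False)
    result.selection.to_json(out_dir / "selection.json")
    if result.selection.correlation_matrix is not None:
        result.selection.correlation_matrix.to_csv(out_dir / "feature_correlations.csv")
    result.model.to_json(out_dir / "model.json")
    result.test_confusion.to_dataframe().to_csv(out_dir / "test_confusion.csv")
    report = {
        "features_used": result.features_used,
        "retained_features": result.selection.retained,
        "train_overall_accuracy_percent": result.train_metrics.overall_percent,
        "test_overall_accuracy_percent": result.test_metrics.overall_percent,
        "test_recall_percent": result.test_metrics.recall_percent_rounded,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
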