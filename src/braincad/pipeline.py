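"""End-to-end orchestration of the CAD pipeline over an image corpus.

Three ablation modes control which stages run before feature extraction:

* ``raw``       — NLBP features on the original images;
* ``enhanced``  — retinex enhancement, then NLBP features;
* ``full``      — enhancement, maximum-entropy segmentation, then NLBP
                  features restricted to the segmented region.

Every run is fully determined by its configuration and seed.  Reports mirror
the conventional layouts: a per-image segmentation table (one row per
pathological image plus an Average row), per-fold classification tables
(classifier x fold) and fold-averaged summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import ClassifierSpec
from .enhancement import TSSRParams, tssr_enhance
from .evaluation import (
    METRIC_NAMES,
    FoldPlan,
    MetricSet,
    average_metrics,
    confusion_from_masks,
    cross_validate,
    metrics,
    round_half_up,
)
from .features import NLBPParams, feature_names, nlbp_features
from .segmentation import MorphParams, segment
from .synthetic import PhantomSpec, generate_corpus

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "extract_features"]

MODES = ("raw", "enhanced", "full")
FOLD_TABLE_COLUMNS = ("TPR", "TNR", "PPV", "F", "AUC", "accuracy")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: mode, stage parameters, classifiers, folds."""

    mode: str = "full"
    tssr: TSSRParams = field(default_factory=TSSRParams)
    morph: MorphParams = field(default_factory=MorphParams)
    nlbp: NLBPParams = field(default_factory=NLBPParams)
    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec(kind="svm_rbf"),
        ClassifierSpec(kind="knn"),
        ClassifierSpec(kind="gentleboost"),
        ClassifierSpec(kind="rf"),
    )
    cv: FoldPlan = field(default_factory=FoldPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML file with per-stage sections
        (``tssr:``, ``morph:``, ``nlbp:``, ``clf:``, ``cv:``)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        seed = int(data.get("seed", 0))
        kinds = data.get("clf", {}).get("kinds", ["svm_rbf", "knn", "gentleboost", "rf"])
        clf_opts = {k: v for k, v in data.get("clf", {}).items() if k != "kinds"}
        return cls(
            mode=data.get("mode", "full"),
            tssr=TSSRParams(**data.get("tssr", {})),
            morph=MorphParams(**data.get("morph", {})),
            nlbp=NLBPParams(**data.get("nlbp", {})),
            classifiers=tuple(ClassifierSpec(kind=k, **clf_opts) for k in kinds),
            cv=FoldPlan(n_folds=int(data.get("cv", {}).get("n_folds", 5)), seed=seed),
            seed=seed,
        )


@dataclass
class PipelineReport:
    """Outputs of one run: features, CV metrics, segmentation metrics."""

    config: PipelineConfig
    features: pd.DataFrame
    fold_metrics: dict[str, list[MetricSet]]
    summary_metrics: dict[str, MetricSet]
    segmentation_table: pd.DataFrame | None

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for clf, folds in self.fold_metrics.items():
            for i, m in enumerate(folds, start=1):
                rows.append({"Classifier": clf, "5-FCV": f"{i}st Fold" if i == 1
                             else f"{i}nd Fold" if i == 2 else f"{i}rd Fold" if i == 3
                             else f"{i}th Fold",
                             **{c: m.as_dict()[c] for c in FOLD_TABLE_COLUMNS}})
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {"Classifier": clf, **{c: m.as_dict()[c] for c in FOLD_TABLE_COLUMNS}}
            for clf, m in self.summary_metrics.items()
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.csv", index=False)
        self.fold_table().to_csv(out / "fold_metrics.csv", index=False)
        self.summary_table().to_csv(out / "summary_metrics.csv", index=False)
        if self.segmentation_table is not None:
            self.segmentation_table.to_csv(out / "segmentation_metrics.csv", index=False)
        manifest = {
            "version": __version__,
            "seed": self.config.seed,
            "config": _config_dict(self.config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["classifiers"] = [dataclasses.asdict(c) for c in config.classifiers]
    return d


def extract_features(
    image: np.ndarray, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray | None]:
    """Run the mode-appropriate stages on one image.

    Returns the normalized NLBP feature vector and, in ``full`` mode, the
    predicted segmentation mask (``None`` otherwise).
    """
    if config.mode == "raw":
        return nlbp_features(image, params=config.nlbp).normalized, None
    enhanced = tssr_enhance(image, config.tssr)
    if config.mode == "enhanced":
        return nlbp_features(enhanced, params=config.nlbp).normalized, None
    mask, _ = segment(enhanced, config.morph)
    return nlbp_features(enhanced, mask, params=config.nlbp).normalized, mask


def run_pipeline(
    config: PipelineConfig,
    corpus: list[tuple[np.ndarray, np.ndarray | None, int]] | None = None,
    phantom_spec: PhantomSpec | None = None,
    n_healthy: int = 45,
    n_pathological: int = 190,
) -> PipelineReport:
    """Execute the pipeline on a corpus of ``(image, truth_mask, label)``.

    When no corpus is supplied, a synthetic one is generated from
    ``phantom_spec`` (seeded by ``config.seed``).  Truth masks, where present
    and non-empty, yield the per-image segmentation table in ``full`` mode.
    """
    if corpus is None:
        corpus = generate_corpus(
            n_healthy, n_pathological, phantom_spec or PhantomSpec(), seed=config.seed
        )
    if not corpus:
        raise ValueError("empty corpus")

    rows = []
    seg_rows = []
    labels = []
    for idx, (image, truth_mask, label) in enumerate(corpus):
        feats, pred_mask = extract_features(image, config)
        rows.append(feats)
        labels.append(label)
        if (
            pred_mask is not None
            and truth_mask is not None
            and np.asarray(truth_mask).any()
        ):
            m = metrics(confusion_from_masks(pred_mask, truth_mask))
            seg_rows.append({"Sample image": idx + 1, **m.as_dict()})

    X = np.vstack(rows)
    y = np.asarray(labels)
    feature_df = pd.DataFrame(X, columns=feature_names(config.nlbp))
    feature_df["label"] = y

    fold_metrics: dict[str, list[MetricSet]] = {}
    summary: dict[str, MetricSet] = {}
    for spec in config.classifiers:
        per_fold, avg = cross_validate(X, y, spec, config.cv)
        fold_metrics[spec.kind] = per_fold
        summary[spec.kind] = avg

    seg_table = None
    if seg_rows:
        seg_table = pd.DataFrame(seg_rows)
        avg_row = {"Sample image": "Average"}
        for name in METRIC_NAMES:
            vals = [r[name] for r in seg_rows if r[name] is not None]
            avg_row[name] = round_half_up(float(np.mean(vals))) if vals else None
        seg_table = pd.concat([seg_table, pd.DataFrame([avg_row])], ignore_index=True)

    return PipelineReport(
        config=config,
        features=feature_df,
        fold_metrics=fold_metrics,
        summary_metrics=summary,
        segmentation_table=seg_table,
    )
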