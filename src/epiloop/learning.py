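"""Supervised learning over candidate pairs: splitting, training, prediction,
evaluation and feature-importance reporting.

The default classifier is a random forest (500 trees, sqrt-features per
split); AdaBoost, gradient boosting, an SVM and a small neural network are
available behind the same interface since the approach is classifier-
agnostic.  Features are the min/max pair encodings of every assay feature
plus the genomic distance between anchors and the segment orders within the
TAD; the distance can be excluded to measure how much of the performance is
distance-driven.

Train/test splits are random at 80/20 by default and can be drawn at the
pair, TAD or chromosome level — group-level splits keep whole TADs or
chromosomes on one side, which is how cross-domain and cross-chromosome
generalization is measured without leakage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import IntegrityError, ValidationError
from .pairing import interaction_coverage, pair_feature_columns

MODEL_FORMAT_VERSION = 1

CLASSIFIERS = ("random_forest", "adaboost", "gbm", "svm", "neural")


@dataclass
class SplitSpec:
    """How to partition labeled pairs into train and test sets."""

    train_fraction: float = 0.8
    seed: int = 0
    level: str = "pair"  # pair | tad | chromosome | genome

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValidationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.level not in ("pair", "tad", "chromosome", "genome"):
            raise ValidationError(f"unknown split level {self.level!r}")


def split(pairs: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seed-reproducible train/test partition.

    ``level='tad'`` / ``'chromosome'`` assign whole groups to one side;
    ``'pair'`` (and ``'genome'``, which treats the genome as one pool)
    sample individual pairs.
    """
    if len(pairs) < 2:
        raise ValidationError("need at least 2 pairs to split")
    rng = np.random.default_rng(spec.seed)
    if spec.level in ("pair", "genome"):
        n = len(pairs)
        n_train = int(round(spec.train_fraction * n))
        if n_train in (0, n):
            raise ValidationError("degenerate split: one side would be empty")
        perm = rng.permutation(n)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    else:
        key = {"tad": "tad_id", "chromosome": "chrom"}[spec.level]
        if key not in pairs.columns:
            raise ValidationError(f"split level {spec.level!r} needs column {key!r}")
        groups = pairs[key].unique()
        groups = groups[np.argsort(groups)]
        perm = rng.permutation(len(groups))
        n_train_groups = int(round(spec.train_fraction * len(groups)))
        n_train_groups = min(max(n_train_groups, 1), len(groups) - 1)
        if len(groups) < 2:
            raise ValidationError(f"need >= 2 groups at level {spec.level!r} to split")
        train_groups = set(groups[perm[:n_train_groups]])
        mask = pairs[key].isin(train_groups).to_numpy()
        train_idx, test_idx = np.where(mask)[0], np.where(~mask)[0]
    train = pairs.iloc[train_idx].reset_index(drop=True)
    test = pairs.iloc[test_idx].reset_index(drop=True)
    return train, test


@dataclass
class TrainedModel:
    """A fitted pair classifier plus its feature contract and importances."""

    kind: str
    estimator: Any
    feature_names: list[str]
    importances: dict[str, float]
    include_distance: bool = True
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "features": self.feature_names,
                "include_distance": self.include_distance,
                "seed": self.seed,
                "hyperparams": {k: repr(v) for k, v in sorted(self.hyperparams.items())},
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _make_estimator(kind: str, seed: int, hyperparams: dict):
    hp = dict(hyperparams or {})
    if kind == "random_forest":
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if kind == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if kind == "gbm":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if kind == "svm":
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    if kind == "neural":
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)
    raise ValidationError(f"unknown classifier {kind!r} (expected one of {CLASSIFIERS})")


def model_feature_names(pairs: pd.DataFrame, include_distance: bool = True) -> list[str]:
    cols = pair_feature_columns(pairs)
    if not include_distance:
        cols = [c for c in cols if c != "genomic_distance"]
    return cols


def train(
    train_pairs: pd.DataFrame,
    classifier_kind: str = "random_forest",
    hyperparams: dict | None = None,
    class_balance: str = "none",
    include_distance: bool = True,
    seed: int = 0,
) -> TrainedModel:
    """Fit a classifier on labeled pairs.

    ``class_balance='downsample'`` subsamples the majority class to parity
    (seeded); ``'weight'`` uses balanced class weights where the estimator
    supports them; the default trains on the full imbalanced set.
    """
    if "label" not in train_pairs.columns:
        raise ValidationError("training pairs lack a 'label' column")
    labels = train_pairs["label"].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        missing = "positive" if 1 not in classes else "negative"
        raise ValidationError(f"training set has no {missing} pairs")
    if class_balance not in ("none", "downsample", "weight"):
        raise ValidationError(f"unknown class_balance {class_balance!r}")

    df = train_pairs
    hp = dict(hyperparams or {})
    if class_balance == "weight":
        hp.setdefault("class_weight", "balanced")
    elif class_balance == "downsample":
        rng = np.random.default_rng(seed)
        n_min = min((labels == c).sum() for c in classes)
        keep = np.concatenate(
            [
                rng.choice(np.where(labels == c)[0], size=n_min, replace=False)
                for c in classes
            ]
        )
        df = train_pairs.iloc[np.sort(keep)]
        labels = df["label"].to_numpy()

    feature_names = model_feature_names(train_pairs, include_distance)
    X = df[feature_names].to_numpy(dtype=float)
    est = _make_estimator(classifier_kind, seed, hp)
    est.fit(X, labels)

    if hasattr(est, "feature_importances_"):
        imp = est.feature_importances_
    else:
        imp = np.zeros(len(feature_names))
    importances = {f: float(v) for f, v in zip(feature_names, imp)}
    return TrainedModel(
        kind=classifier_kind,
        estimator=est,
        feature_names=feature_names,
        importances=importances,
        include_distance=include_distance,
        seed=seed,
        hyperparams=dict(hyperparams or {}),
    )


def predict(model: TrainedModel, pairs: pd.DataFrame) -> np.ndarray:
    """Probability of interaction per pair; columns aligned by name."""
    if not len(pairs):
        return np.empty(0)
    missing = [c for c in model.feature_names if c not in pairs.columns]
    if missing:
        raise IntegrityError(f"pairs lack model feature column(s): {missing}")
    X = pairs[model.feature_names].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    pos_col = list(model.estimator.classes_).index(1)
    return proba[:, pos_col]


def predict_cross_dataset(
    model: TrainedModel,
    pairs: pd.DataFrame,
    resolution: int | None = None,
) -> np.ndarray:
    """Prediction across datasets whose assay panels differ.

    Model features missing from ``pairs`` are filled with the missing-peak
    sentinel (0 for heights, the resolution for summit distances) after a
    warning; this is the mechanism for applying a model trained on one cell
    line (or species) to another.
    """
    import logging

    missing = [c for c in model.feature_names if c not in pairs.columns]
    if missing:
        logging.getLogger(__name__).warning(
            "filling %d missing feature column(s) with sentinels: %s",
            len(missing),
            missing,
        )
        pairs = pairs.copy()
        for c in missing:
            if c.endswith("_summitdist") and resolution:
                pairs[c] = float(resolution)
            else:
                pairs[c] = 0.0
    return predict(model, pairs)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "config_hash": model.config_hash(),
            "model": model,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"]


@dataclass
class EvaluationReport:
    """Confusion-matrix metrics plus AUROC and truth coverage."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auroc: float
    coverage: float | None = None
    cutoff: float = 0.5

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auroc": self.auroc,
            "coverage": self.coverage,
            "cutoff": self.cutoff,
        }

    def summary(self) -> str:
        lines = [
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}",
            f"accuracy={self.accuracy:.4f} sensitivity={self.sensitivity:.4f} "
            f"specificity={self.specificity:.4f} precision={self.precision:.4f}",
            f"AUROC={self.auroc:.4f}",
        ]
        if self.coverage is not None and not np.isnan(self.coverage):
            lines.append(f"truth coverage={self.coverage:.4f}")
        return "\n".join(lines)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    total = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def evaluate(
    pairs: pd.DataFrame,
    probabilities: np.ndarray,
    truth_interactions=None,
    table: pd.DataFrame | None = None,
    cutoff: float = 0.5,
) -> EvaluationReport:
    """Score predictions against the pairs' labels (and, optionally, against
    the truth interaction set for coverage).

    Confusion counts are taken at ``cutoff``; the AUROC is cutoff-free and
    equals the probability that a randomly chosen interacting pair is ranked
    above a randomly chosen non-interacting one.  Coverage is the fraction of
    truth interactions matched (both anchors) by at least one positive call;
    it needs both the truth records and the segment table, and is reported as
    NaN when no truth is given.
    """
    labels = pairs["label"].to_numpy()
    probabilities = np.asarray(probabilities, dtype=float)
    if len(probabilities) != len(pairs):
        raise ValidationError("probabilities length does not match pairs")
    calls = probabilities >= cutoff
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    tn = int(np.sum(~calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    metrics = confusion_metrics(tp, fp, tn, fn)
    if len(np.unique(labels)) == 2:
        auroc = float(roc_auc_score(labels, probabilities))
    else:
        auroc = float("nan")
    coverage = None
    if truth_interactions is not None:
        if table is None:
            raise ValidationError("coverage needs the segment feature table")
        positive_calls = pairs.loc[calls]
        coverage = interaction_coverage(positive_calls, truth_interactions, table)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, auroc=auroc, coverage=coverage, cutoff=cutoff,
        **metrics,
    )


def chi_square_presence(feature_values: np.ndarray, labels: np.ndarray):
    """Chi-square test of independence on the 2x2 table
    (feature present: value > 0) x (pair label).

    Returns (statistic, p_value, low_confidence) where ``low_confidence``
    flags any expected cell below 5 (the test is still reported).
    """
    present = np.asarray(feature_values) > 0
    labels = np.asarray(labels).astype(bool)
    table = np.array(
        [
            [np.sum(present & labels), np.sum(present & ~labels)],
            [np.sum(~present & labels), np.sum(~present & ~labels)],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), bool((expected < 5).any())


@dataclass
class FeatureReport:
    """Per-feature and per-assay importance summaries."""

    features: pd.DataFrame  # feature, importance, chi2, p_value, low_confidence
    assays: pd.DataFrame  # assay, importance, signal_mean, background_mean


def feature_report(model: TrainedModel, pairs: pd.DataFrame) -> FeatureReport:
    """Rank features by model importance, cross-check with a chi-square test
    of independence, and summarize signal vs background per assay.

    The per-assay signal/background summary is the mean over pairs of the sum
    of the assay's peak heights at both anchors (``pair_min + pair_max`` of
    the height feature), separately for interacting and non-interacting
    pairs.
    """
    labels = pairs["label"].to_numpy()
    rows = []
    for f in model.feature_names:
        stat, p, lowconf = chi_square_presence(pairs[f].to_numpy(), labels)
        rows.append(
            {
                "feature": f,
                "importance": model.importances.get(f, 0.0),
                "chi2": stat,
                "p_value": p,
                "low_confidence": lowconf,
            }
        )
    features = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, ignore_index=True
    )

    assay_rows = []
    assays = sorted(
        {
            f[len("pair_min_"): -len("_height")]
            for f in model.feature_names
            if f.startswith("pair_min_") and f.endswith("_height")
        }
    )
    pos = labels == 1
    for a in assays:
        imp = sum(
            model.importances.get(f"pair_{mm}_{a}_{suffix}", 0.0)
            for mm in ("min", "max")
            for suffix in ("height", "summitdist")
        )
        both_anchor_sum = (
            pairs.get(f"pair_min_{a}_height", 0) + pairs.get(f"pair_max_{a}_height", 0)
        )
        both_anchor_sum = np.asarray(both_anchor_sum, dtype=float)
        assay_rows.append(
            {
                "assay": a,
                "importance": imp,
                "signal_mean": float(both_anchor_sum[pos].mean()) if pos.any() else float("nan"),
                "background_mean": float(both_anchor_sum[~pos].mean()) if (~pos).any() else float("nan"),
            }
        )
    assays_df = pd.DataFrame(assay_rows).sort_values(
        "importance", ascending=False, ignore_index=True
    )
    return FeatureReport(features=features, assays=assays_df)
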