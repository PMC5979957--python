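"""End-to-end convenience wrappers composing the pipeline stages.

These functions mirror the stage order of the supervised-learning workflow
(peaks -> segment features -> filtration -> intra-TAD pairs -> labels ->
split -> train -> evaluate) and exist so the CLI, the tests and reproduction
scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import binning, filtration, learning, pairing
from .filtration import FiltrationConfig
from .learning import EvaluationReport, SplitSpec, TrainedModel
from .synth import SimBundle


@dataclass
class StudyResult:
    table: pd.DataFrame
    retained: pd.DataFrame
    pairs: pd.DataFrame
    train_pairs: pd.DataFrame
    test_pairs: pd.DataFrame
    model: TrainedModel
    report: EvaluationReport
    anchor_coverage: float
    positive_fraction: float


def build_labeled_pairs(
    bundle: SimBundle,
    config: FiltrationConfig | None = None,
    aggregation_mode: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bundle -> (feature table, retained table, labeled featurized pairs)."""
    profile = bundle.profile
    if config is None:
        config = FiltrationConfig.for_interaction_type(profile.interaction_type)
    segments = binning.bin_genome(bundle.chromsizes, profile.resolution)
    table = binning.assign_peaks(
        segments,
        bundle.all_peaks(),
        mode=aggregation_mode,
        assays=[a.name for a in profile.assays],
    )
    retained = filtration.filter_segments(table, config)
    pairs = pairing.enumerate_pairs(retained, bundle.tads)
    pairs = pairing.featurize_pairs(pairs, retained.reset_index(drop=True))
    pairs = pairing.label_pairs(
        pairs, bundle.interactions, retained.reset_index(drop=True)
    )
    return table, retained, pairs


def run_study(
    bundle: SimBundle,
    split_spec: SplitSpec | None = None,
    classifier_kind: str = "random_forest",
    hyperparams: dict | None = None,
    include_distance: bool = True,
    class_balance: str = "none",
    seed: int = 0,
) -> StudyResult:
    """Full supervised run on a simulated bundle; returns every artifact."""
    table, retained, pairs = build_labeled_pairs(bundle)
    spec = split_spec or SplitSpec(seed=seed)
    train_pairs, test_pairs = learning.split(pairs, spec)
    model = learning.train(
        train_pairs,
        classifier_kind=classifier_kind,
        hyperparams=hyperparams,
        include_distance=include_distance,
        class_balance=class_balance,
        seed=seed,
    )
    probs = learning.predict(model, test_pairs)
    report = learning.evaluate(
        test_pairs,
        probs,
        truth_interactions=bundle.interactions,
        table=retained.reset_index(drop=True),
    )
    n_pos = int(pairs["label"].sum())
    n_neg = len(pairs) - n_pos
    return StudyResult(
        table=table,
        retained=retained,
        pairs=pairs,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        model=model,
        report=report,
        anchor_coverage=filtration.anchor_segment_coverage(
            retained, bundle.interactions
        ),
        positive_fraction=n_pos / n_neg if n_neg else float("nan"),
    )
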