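"""Segment filtration: discard likely non-interacting loci before pairing.

Two gates are applied, mirroring how loop anchors are selected in ChIA-PET
style analyses:

1. **Mediating protein** — only segments carrying a peak of the protein that
   mediates the interaction class (CTCF for architectural loops and Hi-C
   loops, RNAP II for transcriptional loops) are retained.  For Hi-C heatmaps
   there is no single mediator and no filtration is applied.
2. **Key-feature score** — each segment is scored by the number of
   anchor-enriched "key" assays with a peak present (height > 0), and must
   reach ``min_key_score``.  The score is a presence count, so it is
   threshold-free per assay and monotone in the key set.

The default key sets are the assays enriched at the anchors of each
interaction class: {CTCF, SA1, RAD21, SMC3, ZNF143} for CTCF/Hi-C loops and
{H3K4me1, H3K4me3, H3K27ac} for RNAP II interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import table_assays
from .errors import ValidationError

CTCF_KEY_FEATURES = ("CTCF", "SA1", "RAD21", "SMC3", "ZNF143")
RNAPII_KEY_FEATURES = ("H3K4me1", "H3K4me3", "H3K27ac")


@dataclass
class FiltrationConfig:
    """Which mediator gates segments and which key assays score them.

    ``mediating_assay=None`` together with an empty key set and threshold 0
    is the pass-through configuration used for Hi-C heatmaps.
    """

    mediating_assay: str | None = "CTCF"
    key_features: tuple[str, ...] = CTCF_KEY_FEATURES
    min_key_score: int = 1

    def __post_init__(self):
        self.key_features = tuple(self.key_features)
        if self.min_key_score < 0:
            raise ValidationError("min_key_score must be >= 0")

    @staticmethod
    def for_interaction_type(kind: str) -> "FiltrationConfig":
        """Presets per interaction class: ``ctcf``, ``rnapii``, ``hic_loops``
        (CTCF-mediated), or ``hic_heatmap`` (no filtration)."""
        kind = kind.lower()
        if kind in ("ctcf", "hic_loops"):
            return FiltrationConfig("CTCF", CTCF_KEY_FEATURES, 1)
        if kind == "rnapii":
            return FiltrationConfig("RNAPII", RNAPII_KEY_FEATURES, 1)
        if kind == "hic_heatmap":
            return FiltrationConfig(None, (), 0)
        raise ValidationError(
            f"unknown interaction type {kind!r} "
            "(expected ctcf|rnapii|hic_loops|hic_heatmap)"
        )

    def validate_against(self, table: pd.DataFrame) -> None:
        assays = set(table_assays(table))
        if self.mediating_assay is not None and self.mediating_assay not in assays:
            raise ValidationError(
                f"mediating assay {self.mediating_assay!r} not in table assays {sorted(assays)}"
            )
        missing = [k for k in self.key_features if k not in assays]
        if missing:
            raise ValidationError(
                f"key features {missing} not in table assays {sorted(assays)}"
            )


def key_feature_score(table: pd.DataFrame, key_features) -> pd.Series:
    """Number of key assays with a peak (height > 0) at each segment."""
    assays = set(table_assays(table))
    missing = [k for k in key_features if k not in assays]
    if missing:
        raise ValidationError(f"unknown key feature(s) {missing}")
    if not key_features:
        return pd.Series(np.zeros(len(table), dtype=np.int64), index=table.index)
    present = np.column_stack(
        [(table[f"{k}_height"].to_numpy() > 0) for k in key_features]
    )
    return pd.Series(present.sum(axis=1).astype(np.int64), index=table.index)


def filter_segments(table: pd.DataFrame, config: FiltrationConfig) -> pd.DataFrame:
    """Return the retained rows of the feature table.

    A segment is kept iff the mediating assay has a peak there (or no mediator
    is configured) and its key-feature score reaches the threshold.  An empty
    result is legal (downstream pairing yields zero pairs).
    """
    config.validate_against(table)
    mask = np.ones(len(table), dtype=bool)
    if config.mediating_assay is not None:
        mask &= table[f"{config.mediating_assay}_height"].to_numpy() > 0
    score = key_feature_score(table, config.key_features).to_numpy()
    mask &= score >= config.min_key_score
    out = table.loc[mask].copy()
    out.attrs.update(table.attrs)
    return out


@dataclass
class FiltrationReport:
    n_input: int
    n_retained: int
    anchor_coverage: float | None = None  # fraction of truth anchors retained
    coverage_by_threshold: dict[int, float] = field(default_factory=dict)


def anchor_segment_coverage(retained: pd.DataFrame, interactions, resolution=None) -> float:
    """Fraction of truth anchors overlapped by at least one retained segment."""
    records = list(interactions)
    if not records:
        return float("nan")
    by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in retained.groupby("chrom", sort=False)
    }
    hit = 0
    total = 0
    for r in records:
        for a_start, a_end in ((r.left_start, r.left_end), (r.right_start, r.right_end)):
            total += 1
            if r.chrom not in by_chrom:
                continue
            starts, ends = by_chrom[r.chrom]
            lo = np.searchsorted(ends, a_start, side="right")
            hi = np.searchsorted(starts, a_end, side="left")
            if hi > lo:
                hit += 1
    return hit / total


def threshold_coverage_report(
    table: pd.DataFrame,
    config: FiltrationConfig,
    interactions=None,
    max_threshold: int | None = None,
) -> FiltrationReport:
    """Retention and truth-anchor coverage as a function of ``min_key_score``.

    Replicates the manual tuning loop: the caller inspects how coverage of
    experimental anchors decays as the threshold rises and picks the operating
    point.
    """
    retained = filter_segments(table, config)
    report = FiltrationReport(n_input=len(table), n_retained=len(retained))
    if interactions is not None:
        report.anchor_coverage = anchor_segment_coverage(retained, interactions)
        hi = max_threshold if max_threshold is not None else len(config.key_features)
        for thr in range(0, hi + 1):
            cfg = FiltrationConfig(config.mediating_assay, config.key_features, thr)
            report.coverage_by_threshold[thr] = anchor_segment_coverage(
                filter_segments(table, cfg), interactions
            )
    return report
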