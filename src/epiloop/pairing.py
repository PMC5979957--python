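"""Intra-TAD candidate-pair enumeration, featurization and labeling.

All pairs of retained segments within one TAD are candidates; cross-TAD and
cross-chromosome pairs are never formed (the large majority of chromatin
interactions are intra-domain).  A segment belongs to a TAD iff its center
lies inside the TAD interval, so border segments have a unique membership;
segments outside every TAD are excluded.

Each pair is encoded anchor-order-invariantly by the elementwise minimum and
maximum of the two segments' feature vectors (columns ``pair_min_<f>`` /
``pair_max_<f>``), plus the center-to-center genomic distance and the 0-based
ranks (``left_order`` / ``right_order``) of the segments among retained
segments of the TAD.

Labeling against experimental interactions uses anchor overlap: a pair is
positive iff some interaction on the same chromosome has its left anchor
overlapping the pair's left segment AND its right anchor overlapping the
right segment (>= 1 bp each, ``mode='overlap'``).  ``mode='strict'`` instead
requires each anchor's midpoint to fall inside the segment (exact-bin
matching at matched resolutions).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .binning import segment_center
from .errors import IntegrityError, ValidationError
from .io import InteractionRecord, TadRecord

PAIR_META_COLUMNS = [
    "tad_id",
    "chrom",
    "left_row",
    "right_row",
    "left_index",
    "right_index",
    "left_start",
    "left_end",
    "right_start",
    "right_end",
    "left_order",
    "right_order",
    "genomic_distance",
]


def assign_tads(table: pd.DataFrame, tads: list[TadRecord]) -> pd.Series:
    """TAD id per table row (by segment center), or ``None`` outside all TADs."""
    out = pd.Series([None] * len(table), index=table.index, dtype=object)
    by_chrom: dict[str, list[TadRecord]] = {}
    for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, grp in table.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        ts = by_chrom[chrom]
        starts = np.array([t.start for t in ts])
        ends = np.array([t.end for t in ts])
        centers = segment_center(grp["start"].to_numpy(), grp["end"].to_numpy())
        pos = np.searchsorted(starts, centers, side="right") - 1
        ok = (pos >= 0) & (centers < ends[np.clip(pos, 0, None)])
        ids = np.array([t.tad_id for t in ts], dtype=object)
        vals = np.where(ok, ids[np.clip(pos, 0, None)], None)
        out.loc[grp.index] = vals
    return out


def enumerate_pairs(retained: pd.DataFrame, tads: list[TadRecord]) -> pd.DataFrame:
    """All C(n, 2) ordered segment pairs per TAD over the retained table.

    Output rows are ordered by (tad, left bin index, right bin index); the
    ``*_row`` columns are positional indices into ``retained`` and
    ``*_order`` the within-TAD ranks.  Segments outside every TAD contribute
    no pairs.
    """
    retained = retained.reset_index(drop=True)
    tad_of = assign_tads(retained, tads)
    frames = []
    tad_order = {t.tad_id: (t.chrom, t.start) for t in tads}
    groups = sorted(
        ((tid, idx) for tid, idx in retained.groupby(tad_of, sort=False).groups.items()),
        key=lambda kv: tad_order[kv[0]],
    )
    starts = retained["start"].to_numpy()
    ends = retained["end"].to_numpy()
    centers = segment_center(starts, ends)
    for tad_id, idx in groups:
        rows = np.sort(np.asarray(idx, dtype=np.int64))
        n = len(rows)
        if n < 2:
            continue
        li, ri = np.triu_indices(n, k=1)
        frames.append(
            pd.DataFrame(
                {
                    "tad_id": tad_id,
                    "chrom": retained["chrom"].iloc[rows[0]],
                    "left_row": rows[li],
                    "right_row": rows[ri],
                    "left_index": retained["index"].to_numpy()[rows[li]],
                    "right_index": retained["index"].to_numpy()[rows[ri]],
                    "left_start": starts[rows[li]],
                    "left_end": ends[rows[li]],
                    "right_start": starts[rows[ri]],
                    "right_end": ends[rows[ri]],
                    "left_order": li,
                    "right_order": ri,
                    "genomic_distance": centers[rows[ri]] - centers[rows[li]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_META_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    if (out["genomic_distance"] <= 0).any():
        raise IntegrityError("non-positive genomic distance between paired segments")
    return out


def pair_feature_columns(table_or_pairs: pd.DataFrame) -> list[str]:
    """The learnable feature columns of a pair table."""
    return [
        c
        for c in table_or_pairs.columns
        if c.startswith(("pair_min_", "pair_max_"))
    ] + ["genomic_distance", "left_order", "right_order"]


def featurize_pairs(pairs: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Attach min/max pair encodings of every feature column of ``table``.

    The encoding is symmetric in the two anchors, so it is invariant to which
    segment is called left or right.
    """
    table = table.reset_index(drop=True)
    feature_cols = [
        c for c in table.columns if c.endswith(("_height", "_summitdist"))
    ]
    lrow = pairs["left_row"].to_numpy()
    rrow = pairs["right_row"].to_numpy()
    if len(pairs) and (lrow.max() >= len(table) or rrow.max() >= len(table)):
        raise IntegrityError("pair refers to a segment row missing from the feature table")
    out = pairs.copy()
    feats = {}
    for c in feature_cols:
        vals = table[c].to_numpy()
        lv, rv = vals[lrow], vals[rrow]
        feats[f"pair_min_{c}"] = np.minimum(lv, rv)
        feats[f"pair_max_{c}"] = np.maximum(lv, rv)
    out = pd.concat([out, pd.DataFrame(feats, index=out.index)], axis=1)
    return out


def _anchor_overlap_rows(chrom_index, chrom, a_start, a_end, mode):
    """Positional rows of segments matched by an anchor on one chromosome."""
    if chrom not in chrom_index:
        return np.empty(0, dtype=np.int64)
    rows, starts, ends = chrom_index[chrom]
    if mode == "strict":
        mid = a_start + (a_end - a_start) // 2
        lo = np.searchsorted(ends, mid, side="right")
        hi = np.searchsorted(starts, mid + 1, side="left")
    elif mode == "overlap":
        lo = np.searchsorted(ends, a_start, side="right")
        hi = np.searchsorted(starts, a_end, side="left")
    else:
        raise ValidationError(f"unknown labeling mode {mode!r} (expected strict|overlap)")
    return rows[lo:hi]


def _chrom_index(table: pd.DataFrame):
    """Per-chromosome (row positions, starts, ends) sorted by start."""
    table = table.reset_index(drop=True)
    index = {}
    for chrom, grp in table.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        index[chrom] = (
            grp.index.to_numpy(dtype=np.int64),
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
        )
    return index


def positive_pair_keys(
    interactions, table: pd.DataFrame, mode: str = "overlap"
) -> set[tuple[int, int]]:
    """Set of (left_row, right_row) segment pairs matching any interaction."""
    cindex = _chrom_index(table)
    keys: set[tuple[int, int]] = set()
    for r in interactions:
        lrows = _anchor_overlap_rows(cindex, r.chrom, r.left_start, r.left_end, mode)
        rrows = _anchor_overlap_rows(cindex, r.chrom, r.right_start, r.right_end, mode)
        for a, b in itertools.product(lrows, rrows):
            if a == b:
                continue
            keys.add((a, b) if a < b else (b, a))
    return keys


def label_pairs(
    pairs: pd.DataFrame,
    interactions,
    table: pd.DataFrame,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Attach a binary ``label`` column: 1 iff both anchors of some
    experimental interaction overlap the pair's two segments respectively.

    Labels do not depend on pair order or on the order in which an
    interaction's anchors were given (both are canonicalized).
    """
    keys = positive_pair_keys(interactions, table, mode)
    lrow = pairs["left_row"].to_numpy()
    rrow = pairs["right_row"].to_numpy()
    label = np.fromiter(
        ((int((a, b) in keys or (b, a) in keys)) for a, b in zip(lrow, rrow)),
        dtype=np.int8,
        count=len(pairs),
    )
    out = pairs.copy()
    out["label"] = label
    return out


def pairs_to_interactions(pairs: pd.DataFrame) -> list[InteractionRecord]:
    """Express pair rows as anchor-pair records (for BEDPE output)."""
    return [
        InteractionRecord(
            row.chrom,
            int(row.left_start),
            int(row.left_end),
            int(row.right_start),
            int(row.right_end),
        )
        for row in pairs.itertuples(index=False)
    ]


def interaction_coverage(
    positive_pairs: pd.DataFrame,
    interactions,
    table: pd.DataFrame,
    mode: str = "overlap",
) -> float:
    """Fraction of truth interactions matched (both anchors) by >= 1 pair."""
    records = list(interactions)
    if not records:
        return float("nan")
    pair_keys = {
        (int(a), int(b))
        for a, b in zip(positive_pairs["left_row"], positive_pairs["right_row"])
    }
    cindex = _chrom_index(table)
    covered = 0
    for r in records:
        lrows = _anchor_overlap_rows(cindex, r.chrom, r.left_start, r.left_end, mode)
        rrows = _anchor_overlap_rows(cindex, r.chrom, r.right_start, r.right_end, mode)
        hit = any(
            ((a, b) if a < b else (b, a)) in pair_keys
            for a, b in itertools.product(lrows, rrows)
            if a != b
        )
        covered += int(hit)
    return covered / len(records)


def write_pair_table(pairs: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        pairs.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
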