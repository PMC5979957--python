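"""Distance-stratified scoring of Hi-C contacts and three-class labeling.

Raw Hi-C counts are dominated by genomic distance: nearly everything inside a
TAD looks "in contact".  To separate physical interactions from mere
proximity, each contact is scored *relative to all contacts at the same
genomic distance* within its stratum (a TAD by default, a chromosome for
low-resolution population heatmaps).  The score adopted here is the
distance-stratified midrank percentile

    dscore(c) = (#{stronger} + 0.5 * #{equal, excluding self}) / N_d

over the N_d bin pairs of the stratum at that distance, so ``dscore`` lies in
[0, 1] and **low means stronger than expected at that distance**.  Bin pairs
with no recorded contact are included as count-0 members of their population
(otherwise sparse TADs would look uniformly loop-rich).  The percentile is
rank-based, hence invariant to sequencing depth.

Note this percentile construction is one concrete realization of a
"score relative to genomic distance"; any monotone distance-normalized score
with the same [0, 1] range would plug into the same thresholding rule.

Contacts are then labeled with a threshold theta (default 0.15):

* ``interaction``      iff dscore <= theta,
* ``non_interaction``  iff dscore >= 1 - theta,
* ``no_class``         otherwise (excluded from training).

theta = 0.5 collapses the no-class band to nothing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .io import TadRecord
from .pairing import featurize_pairs

DEFAULT_THETA = 0.15

STATE_INTERACTION = "interaction"
STATE_NON_INTERACTION = "non_interaction"
STATE_NO_CLASS = "no_class"


def _tad_bin_ranges(tads: list[TadRecord], resolution: int) -> dict[str, list[tuple]]:
    """Per chromosome, (first_bin, last_bin_exclusive, tad_id) per TAD.

    A bin belongs to a TAD iff the bin center lies inside the TAD, matching
    segment-to-TAD assignment in pairing.
    """
    out: dict[str, list[tuple]] = {}
    for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
        # bins whose center (b + 0.5) * res falls in [start, end)
        b0 = int(np.ceil(t.start / resolution - 0.5))
        b1 = int(np.ceil(t.end / resolution - 0.5))
        if b1 > b0:
            out.setdefault(t.chrom, []).append((b0, b1, t.tad_id))
    return out


def _midrank_dscores(counts: np.ndarray, n_population: int) -> np.ndarray:
    """Midrank percentile of each recorded count within a population that
    also contains ``n_population - len(counts)`` implicit zeros."""
    n_rec = len(counts)
    n_zero = n_population - n_rec
    if n_zero < 0:
        raise IntegrityError(
            f"{n_rec} recorded contacts exceed the {n_population} possible bin pairs"
        )
    order = np.argsort(counts, kind="stable")
    sorted_counts = counts[order]
    # for each value: number of recorded counts strictly greater / equal
    hi = n_rec - np.searchsorted(sorted_counts, counts, side="right")  # greater
    eq = (
        np.searchsorted(sorted_counts, counts, side="right")
        - np.searchsorted(sorted_counts, counts, side="left")
    )  # equal among recorded, including self
    zeros_equal = np.where(counts == 0, n_zero, 0)
    greater = hi + np.where(counts == 0, 0, 0)  # implicit zeros are never greater
    ties_excl_self = eq - 1 + zeros_equal
    return (greater + 0.5 * ties_excl_self) / n_population


def distance_score(
    contacts: pd.DataFrame,
    tads: list[TadRecord] | None = None,
    stratum: str = "tad",
    chromsizes: dict[str, int] | None = None,
    resolution: int | None = None,
) -> pd.DataFrame:
    """Score recorded contacts by distance-stratified midrank percentile.

    ``stratum='tad'`` (default, matching per-TAD training) requires ``tads``;
    contacts whose two bins do not fall inside one common TAD are dropped.
    ``stratum='chromosome'`` pools each chromosome; ``chromsizes`` then fixes
    the population size per distance (bins with no recorded contact count as
    zeros).  Without ``chromsizes`` the population is the recorded contacts
    only.

    Returns a copy of the recorded contacts with ``distance_bins``,
    ``dscore`` and stratum columns; self-contacts (distance 0) are dropped
    since a single-member population has no meaningful percentile.
    """
    resolution = resolution or contacts.attrs.get("resolution")
    if resolution is None or resolution <= 0:
        raise ValidationError("contacts must carry a positive resolution")
    df = contacts.copy()
    df["distance_bins"] = df["bin_j"] - df["bin_i"]
    df = df[df["distance_bins"] > 0].reset_index(drop=True)

    if stratum == "tad":
        if tads is None:
            raise ValidationError("stratum='tad' requires TAD coordinates")
        ranges = _tad_bin_ranges(tads, resolution)
        tad_id = np.full(len(df), None, dtype=object)
        n_bins = np.zeros(len(df), dtype=np.int64)
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom not in ranges:
                continue
            for b0, b1, tid in ranges[chrom]:
                inside = (
                    (grp["bin_i"].to_numpy() >= b0)
                    & (grp["bin_j"].to_numpy() < b1)
                )
                rows = grp.index.to_numpy()[inside]
                tad_id[rows] = tid
                n_bins[rows] = b1 - b0
        keep = pd.notna(tad_id)
        df = df.loc[keep].reset_index(drop=True)
        df["stratum"] = tad_id[keep]
        size_of = dict(
            zip(df["stratum"], n_bins[keep])
        )
        group_cols = ["stratum", "distance_bins"]
        pop_size = lambda key: size_of[key[0]] - key[1]
    elif stratum == "chromosome":
        df["stratum"] = df["chrom"]
        if chromsizes is not None:
            nb = {c: -(-l // resolution) for c, l in chromsizes.items()}
            pop_size = lambda key: max(nb.get(key[0], 0) - key[1], 0)
        else:
            pop_size = None
        group_cols = ["stratum", "distance_bins"]
    else:
        raise ValidationError(f"unknown stratum {stratum!r} (expected tad|chromosome)")

    dscore = np.empty(len(df))
    for key, grp in df.groupby(group_cols, sort=False):
        counts = grp["count"].to_numpy(dtype=float)
        n_pop = pop_size(key) if pop_size is not None else len(counts)
        n_pop = max(n_pop, len(counts))
        dscore[grp.index.to_numpy()] = _midrank_dscores(counts, n_pop)
    df["dscore"] = dscore
    df.attrs["resolution"] = int(resolution)
    return df


def classify_contacts(scored: pd.DataFrame, theta: float = DEFAULT_THETA) -> pd.DataFrame:
    """Three-class labeling of scored contacts by threshold ``theta``."""
    if not (0 < theta <= 0.5):
        raise ValidationError(f"theta must be in (0, 0.5], got {theta}")
    out = scored.copy()
    d = out["dscore"].to_numpy()
    state = np.full(len(out), STATE_NO_CLASS, dtype=object)
    state[d <= theta] = STATE_INTERACTION
    state[d >= 1 - theta] = STATE_NON_INTERACTION
    out["state"] = state
    out.attrs.update(scored.attrs)
    out.attrs["theta"] = float(theta)
    return out


def contacts_to_pairs(
    classified: pd.DataFrame,
    table: pd.DataFrame,
    tads: list[TadRecord],
) -> pd.DataFrame:
    """Turn classified contacts into labeled, featurized candidate pairs.

    ``interaction`` contacts become positives, ``non_interaction`` negatives;
    ``no_class`` contacts are dropped and never reach training.  Bin indices
    map one-to-one onto segment rows of the feature table (which must be at
    the contact resolution).
    """
    res = classified.attrs.get("resolution")
    if res is not None and table.attrs.get("resolution") not in (None, res):
        raise ValidationError(
            f"contact resolution {res} != feature-table resolution "
            f"{table.attrs.get('resolution')}"
        )
    table = table.reset_index(drop=True)
    row_of = {
        (chrom, idx): row
        for row, (chrom, idx) in enumerate(zip(table["chrom"], table["index"]))
    }
    df = classified[classified["state"] != STATE_NO_CLASS]
    if not len(df):
        return pd.DataFrame()
    order_in_tad: dict[str, dict[int, int]] = {}
    from .pairing import assign_tads

    tad_of = assign_tads(table, tads)
    for tid, idx in table.groupby(tad_of, sort=False).groups.items():
        rows = np.sort(np.asarray(idx, dtype=np.int64))
        order_in_tad[tid] = {int(r): k for k, r in enumerate(rows)}

    recs = []
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    from .binning import segment_center

    centers = segment_center(starts, ends)
    for row in df.itertuples(index=False):
        try:
            lrow = row_of[(row.chrom, int(row.bin_i))]
            rrow = row_of[(row.chrom, int(row.bin_j))]
        except KeyError as exc:
            raise IntegrityError(
                f"contact bin {exc.args[0]} has no segment in the feature table"
            ) from exc
        tid = getattr(row, "stratum", None)
        orders = order_in_tad.get(tid, {})
        recs.append(
            {
                "tad_id": tid,
                "chrom": row.chrom,
                "left_row": lrow,
                "right_row": rrow,
                "left_index": int(row.bin_i),
                "right_index": int(row.bin_j),
                "left_start": int(starts[lrow]),
                "left_end": int(ends[lrow]),
                "right_start": int(starts[rrow]),
                "right_end": int(ends[rrow]),
                "left_order": orders.get(lrow, -1),
                "right_order": orders.get(rrow, -1),
                "genomic_distance": int(centers[rrow] - centers[lrow]),
                "label": 1 if row.state == STATE_INTERACTION else 0,
            }
        )
    pairs = pd.DataFrame(recs)
    return featurize_pairs(pairs, table)


def write_scored_contacts(scored: pd.DataFrame, path, header: str | None = None) -> None:
    cols = [c for c in ["chrom", "bin_i", "bin_j", "count", "distance_bins",
                        "stratum", "dscore", "state"] if c in scored.columns]
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        scored[cols].to_csv(fh, sep="\t", index=False, float_format="%.6f")
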