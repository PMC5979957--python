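"""Genome binning and per-segment peak featurization.

The genome is tiled into fixed-resolution segments (the operating resolutions
are 1 kb for physical-interaction prediction and 5 kb / 40 kb for contact
heatmaps).  Each segment is then described by two features per assay:

* ``<assay>_height`` — the aggregated signal of peaks overlapping it, and
* ``<assay>_summitdist`` — the distance (bp) from the selected peak's summit
  to the segment center, capped at one resolution.

Segments without a peak for an assay get the sentinel ``(0, resolution)``,
which is monotonically the weakest possible signal.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import PeakRecord

SEGMENT_COLUMNS = ["chrom", "index", "start", "end"]

#: boundary (bp) at or below which peak heights within a segment are combined
#: by maximum; above it they are summed (low-resolution heatmaps accumulate
#: signal instead of resolving individual binding events)
MAX_MODE_RESOLUTION_CUTOFF = 5_000


class Segment(NamedTuple):
    chrom: str
    index: int
    start: int
    end: int
    resolution: int


def segment_center(start, end):
    """Midpoint of a segment, floored to an integer base position."""
    return start + (end - start) // 2


def bin_genome(chromsizes: Mapping[str, int], resolution: int) -> pd.DataFrame:
    """Tile every chromosome into consecutive ``resolution``-sized segments.

    The final segment of a chromosome is truncated at the chromosome end.
    Returns a DataFrame with columns (chrom, index, start, end), sorted by
    chromosome name then index, with ``attrs['resolution']`` set.
    """
    if resolution <= 0:
        raise ValidationError(f"resolution must be positive, got {resolution}")
    frames = []
    for chrom in sorted(chromsizes):
        length = int(chromsizes[chrom])
        if length <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        n = -(-length // resolution)  # ceil
        idx = np.arange(n, dtype=np.int64)
        starts = idx * resolution
        ends = np.minimum(starts + resolution, length)
        frames.append(
            pd.DataFrame({"chrom": chrom, "index": idx, "start": starts, "end": ends})
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SEGMENT_COLUMNS
    )
    out.attrs["resolution"] = int(resolution)
    return out


def resolve_aggregation_mode(mode: str | None, resolution: int) -> str:
    """``max`` at high resolution (<= 5 kb), ``sum`` at low resolution.

    An explicit ``mode`` overrides the automatic choice.
    """
    if mode is None or mode == "auto":
        return "max" if resolution <= MAX_MODE_RESOLUTION_CUTOFF else "sum"
    if mode not in ("max", "sum"):
        raise ValidationError(f"unknown aggregation mode {mode!r} (expected max|sum)")
    return mode


def feature_columns_for_assays(assays: Iterable[str]) -> list[str]:
    cols = []
    for a in assays:
        cols.append(f"{a}_height")
        cols.append(f"{a}_summitdist")
    return cols


def assign_peaks(
    segments: pd.DataFrame,
    peaks: Iterable[PeakRecord],
    mode: str | None = None,
    assays: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Build the per-segment feature table from called peaks.

    A peak contributes to every segment it overlaps.  Per segment and assay:

    * ``mode='max'``: height is the maximum signal among overlapping peaks and
      the summit distance is that of the selected peak (ties broken toward the
      smaller summit distance, then the earlier peak);
    * ``mode='sum'``: height is the sum of signals and the summit distance is
      the minimum over contributing peaks.

    ``mode=None`` auto-selects by resolution (max for <= 5 kb, else sum).
    Summit distances are capped at one resolution so that a far-away summit is
    indistinguishable from the no-peak sentinel.  ``assays`` fixes the assay
    column set (and order) even when some assays have no peaks.
    """
    resolution = segments.attrs.get("resolution")
    if resolution is None:
        raise ValidationError("segments table lacks a declared resolution")
    mode = resolve_aggregation_mode(mode, resolution)

    peaks = list(peaks)
    assay_list = list(assays) if assays is not None else sorted({p.assay for p in peaks})

    table = segments[SEGMENT_COLUMNS].copy()
    n = len(table)
    # per-chromosome row offsets so bin index -> table row is O(1)
    chrom_offsets: dict[str, tuple[int, int]] = {}
    for chrom, grp in table.groupby("chrom", sort=False):
        chrom_offsets[chrom] = (int(grp.index[0]), int(grp["index"].iloc[-1]))
    centers = segment_center(
        table["start"].to_numpy(), table["end"].to_numpy()
    )

    feats = {}
    by_assay: dict[str, list[PeakRecord]] = {a: [] for a in assay_list}
    for p in peaks:
        if p.assay not in by_assay:
            raise ValidationError(
                f"peak assay {p.assay!r} not in the declared assay set {assay_list}"
            )
        by_assay[p.assay].append(p)

    for assay in assay_list:
        height = np.zeros(n)
        sdist = np.full(n, float(resolution))
        # deterministic regardless of input order
        for p in sorted(by_assay[assay], key=lambda p: (p.chrom, p.start, p.end, p.signal)):
            if p.chrom not in chrom_offsets:
                continue
            row0, last_bin = chrom_offsets[p.chrom]
            b0 = max(p.start // resolution, 0)
            b1 = min((p.end - 1) // resolution, last_bin)
            summit = p.summit
            for b in range(b0, b1 + 1):
                row = row0 + b
                d = min(abs(summit - centers[row]), resolution)
                if mode == "max":
                    if p.signal > height[row] or (
                        p.signal == height[row] and height[row] > 0 and d < sdist[row]
                    ):
                        height[row] = p.signal
                        sdist[row] = d
                else:
                    height[row] += p.signal
                    sdist[row] = min(sdist[row], d)
        feats[f"{assay}_height"] = height
        feats[f"{assay}_summitdist"] = sdist

    out = pd.concat([table, pd.DataFrame(feats, index=table.index)], axis=1)
    out.attrs["resolution"] = int(resolution)
    out.attrs["assays"] = assay_list
    out.attrs["aggregation_mode"] = mode
    return out


def table_assays(table: pd.DataFrame) -> list[str]:
    """Assay names recoverable from a feature table's columns."""
    if "assays" in table.attrs:
        return list(table.attrs["assays"])
    return [c[: -len("_height")] for c in table.columns if c.endswith("_height")]


def write_feature_table(table: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        if "resolution" in table.attrs:
            fh.write(f"#resolution={table.attrs['resolution']}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_feature_table(path) -> pd.DataFrame:
    resolution = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("#resolution="):
                resolution = int(line.strip().split("=", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    if resolution is not None:
        table.attrs["resolution"] = resolution
    table.attrs["assays"] = [
        c[: -len("_height")] for c in table.columns if c.endswith("_height")
    ]
    return table
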