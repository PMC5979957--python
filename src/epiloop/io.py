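"""Readers and writers for the plain-text genomic formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention) everywhere in the
package; conversion happens nowhere else.  Formats handled:

* ENCODE narrowPeak (BED6+4) and plain BED6 peak files,
* BED3/BED4 domain (TAD/CCD) files,
* BEDPE anchor-pair interaction files (an optional 7th column carries a
  score such as a PET count; written predictions append a probability),
* two-column ``chrom.sizes`` files,
* sparse contact tables: ``chrom  bin_i  bin_j  count`` at a fixed,
  caller-declared resolution.

Strand is never consumed: none of the downstream operations use it.
Writers produce canonical files (tab-separated, floats at fixed precision)
for which ``write(read(f)) == f`` holds byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "{:.4f}"


def _fmt_signal(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


@dataclass(frozen=True)
class PeakRecord:
    """A called ChIP-seq peak for one assay.

    ``summit_offset`` is the offset of the summit from ``start`` (narrowPeak
    column 10); ``-1`` means unknown, in which case downstream code falls back
    to the peak midpoint.
    """

    chrom: str
    start: int
    end: int
    signal: float
    summit_offset: int
    assay: str
    name: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"peak interval invalid: {self.chrom}:{self.start}-{self.end}"
            )
        if self.signal < 0:
            raise ValidationError(f"negative peak signal {self.signal}")
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.end - self.start):
            raise ValidationError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.end - self.start}"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when the offset is unknown."""
        if self.summit_offset == -1:
            return self.start + (self.end - self.start) // 2
        return self.start + self.summit_offset


@dataclass(frozen=True)
class TadRecord:
    """A topologically associating domain (or chromatin contact domain)."""

    chrom: str
    start: int
    end: int
    tad_id: str

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"TAD interval invalid: {self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class InteractionRecord:
    """An experimental anchor pair (BEDPE semantics), intra-chromosomal,
    with anchors in canonical left-before-right order."""

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    score: float | None = None

    def __post_init__(self):
        for s, e in ((self.left_start, self.left_end), (self.right_start, self.right_end)):
            if s < 0 or e <= s:
                raise ValidationError(f"anchor interval invalid: {s}-{e}")
        if self.score is not None and self.score < 0:
            raise ValidationError(f"negative interaction score {self.score}")

    @staticmethod
    def canonical(chrom, a_start, a_end, b_start, b_end, score=None) -> "InteractionRecord":
        """Order the two anchors left-before-right by start coordinate."""
        if (b_start, b_end) < (a_start, a_end):
            a_start, a_end, b_start, b_end = b_start, b_end, a_start, a_end
        return InteractionRecord(chrom, a_start, a_end, b_start, b_end, score)


@dataclass
class InteractionSet:
    """Experimental interactions plus bookkeeping from parsing."""

    records: list[InteractionRecord] = field(default_factory=list)
    n_dropped_interchrom: int = 0

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _lines(path):
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_narrowpeak(path, assay_label: str) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED6 peak file.

    For 6-column BED input the score column becomes the signal and the summit
    is unknown (``summit_offset = -1``).  Records are returned sorted by
    ``(chrom, start)`` with ``assay_label`` attached.
    """
    peaks = []
    for lineno, cols in _lines(path):
        if len(cols) < 6:
            raise ParseError(
                f"expected >=6 tab-separated columns, got {len(cols)}", path, lineno
            )
        try:
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            if len(cols) >= 10:
                signal = float(cols[6])
                summit = int(cols[9])
            else:
                signal = float(cols[4])
                summit = -1
        except ValueError as exc:
            raise ParseError(f"malformed peak line: {exc}", path, lineno) from exc
        try:
            peaks.append(PeakRecord(chrom, start, end, signal, summit, assay_label, name))
        except ValidationError as exc:
            raise ParseError(str(exc), path, lineno) from exc
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_narrowpeak(peaks: Iterable[PeakRecord], path, header: str | None = None) -> None:
    """Write peaks as narrowPeak; unused columns get the conventional fillers."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        "0",
                        ".",
                        _fmt_signal(p.signal),
                        "-1",
                        "-1",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def read_bedpe(path) -> InteractionSet:
    """Read BEDPE interactions.

    Anchors are canonically ordered left-before-right; inter-chromosomal
    records are dropped (the pipeline predicts within TADs only) and counted
    in ``n_dropped_interchrom``.  A 7th column, when numeric, is kept as the
    record score (e.g. a PET count).
    """
    out = InteractionSet()
    for lineno, cols in _lines(path):
        if len(cols) < 6:
            raise ParseError(
                f"expected >=6 tab-separated columns, got {len(cols)}", path, lineno
            )
        try:
            c1, s1, e1 = cols[0], int(cols[1]), int(cols[2])
            c2, s2, e2 = cols[3], int(cols[4]), int(cols[5])
        except ValueError as exc:
            raise ParseError(f"malformed BEDPE line: {exc}", path, lineno) from exc
        score = None
        if len(cols) >= 7 and cols[6] not in (".", ""):
            try:
                score = float(cols[6])
            except ValueError:
                score = None
        if c1 != c2:
            out.n_dropped_interchrom += 1
            continue
        try:
            out.records.append(InteractionRecord.canonical(c1, s1, e1, s2, e2, score))
        except ValidationError as exc:
            raise ParseError(str(exc), path, lineno) from exc
    if out.n_dropped_interchrom:
        logger.info(
            "dropped %d inter-chromosomal interaction(s) from %s",
            out.n_dropped_interchrom,
            path,
        )
    out.records.sort(
        key=lambda r: (r.chrom, r.left_start, r.left_end, r.right_start, r.right_end)
    )
    return out


def write_bedpe(
    interactions: Iterable[InteractionRecord],
    path,
    probabilities: Iterable[float] | None = None,
    header: str | None = None,
) -> None:
    """Write interactions as BEDPE; a 7th column carries the score, and an
    8th the prediction probability when given."""
    interactions = list(interactions)
    probs = list(probabilities) if probabilities is not None else None
    if probs is not None and len(probs) != len(interactions):
        raise ValidationError("probabilities length does not match interactions")
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for i, r in enumerate(interactions):
            cols = [
                r.chrom,
                str(r.left_start),
                str(r.left_end),
                r.chrom,
                str(r.right_start),
                str(r.right_end),
                _fmt_signal(r.score) if r.score is not None else ".",
            ]
            if probs is not None:
                cols.append(_fmt_signal(probs[i]))
            fh.write("\t".join(cols) + "\n")


def read_bed_tads(path) -> list[TadRecord]:
    """Read TAD coordinates from BED3/BED4 and validate non-overlap.

    Column 4, when present, is the TAD id; otherwise ids ``tad_0001``... are
    assigned in (chrom, start) order.  Overlapping TADs on one chromosome are
    an error.
    """
    raw = []
    for lineno, cols in _lines(path):
        if len(cols) < 3:
            raise ParseError(
                f"expected >=3 tab-separated columns, got {len(cols)}", path, lineno
            )
        try:
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ParseError(f"malformed BED line: {exc}", path, lineno) from exc
        tad_id = cols[3] if len(cols) >= 4 else None
        if start < 0 or end <= start:
            raise ParseError(f"invalid TAD interval {start}-{end}", path, lineno)
        raw.append((chrom, start, end, tad_id))
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    tads = []
    for i, (chrom, start, end, tad_id) in enumerate(raw):
        if tad_id is None:
            tad_id = f"tad_{i + 1:04d}"
        tads.append(TadRecord(chrom, start, end, tad_id))
    for a, b in zip(tads, tads[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(
                f"overlapping TADs on {a.chrom}: {a.tad_id} ({a.start}-{a.end}) and "
                f"{b.tad_id} ({b.start}-{b.end})"
            )
    return tads


def write_bed_tads(tads: Iterable[TadRecord], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for t in sorted(tads, key=lambda t: (t.chrom, t.start)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.tad_id}\n")


def read_chromsizes(path) -> dict[str, int]:
    """Read a two-column ``chrom  length`` file."""
    sizes: dict[str, int] = {}
    for lineno, cols in _lines(path):
        if len(cols) < 2:
            raise ParseError("expected two tab-separated columns", path, lineno)
        try:
            length = int(cols[1])
        except ValueError as exc:
            raise ParseError(f"malformed chromosome length: {cols[1]}", path, lineno) from exc
        if length <= 0:
            raise ParseError(f"non-positive chromosome length {length}", path, lineno)
        sizes[cols[0]] = length
    return sizes


def write_chromsizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


CONTACT_COLUMNS = ["chrom", "bin_i", "bin_j", "count"]


def canonicalize_contacts(df: pd.DataFrame) -> pd.DataFrame:
    """Mirror triples so ``bin_i <= bin_j`` and sum duplicates.

    Summation of duplicates follows the symmetry convention for contact
    matrices: (i, j) and (j, i) are the same entry.
    """
    df = df.copy()
    flip = df["bin_i"].to_numpy() > df["bin_j"].to_numpy()
    bi = np.where(flip, df["bin_j"], df["bin_i"])
    bj = np.where(flip, df["bin_i"], df["bin_j"])
    df["bin_i"], df["bin_j"] = bi, bj
    df = (
        df.groupby(["chrom", "bin_i", "bin_j"], as_index=False, sort=True)["count"]
        .sum()
    )
    return df[CONTACT_COLUMNS]


def read_contacts(path, resolution: int) -> pd.DataFrame:
    """Read a sparse contact table (``chrom  bin_i  bin_j  count``).

    Returns a pixels-style DataFrame with ``attrs['resolution']`` set.  Triples
    with ``bin_i > bin_j`` are mirrored to canonical order; duplicates are
    summed.  Negative counts or bin indices are a validation error.
    """
    if resolution <= 0:
        raise ValidationError(f"resolution must be positive, got {resolution}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=CONTACT_COLUMNS,
            dtype={"chrom": str, "bin_i": np.int64, "bin_j": np.int64, "count": np.float64},
        )
    except ValueError as exc:
        raise ParseError(f"malformed contact table: {exc}", path) from exc
    if len(df) and ((df["bin_i"] < 0).any() or (df["bin_j"] < 0).any()):
        raise ValidationError(f"negative bin index in {path}")
    if len(df) and (df["count"] < 0).any():
        raise ValidationError(f"negative contact count in {path}")
    df = canonicalize_contacts(df)
    df.attrs["resolution"] = int(resolution)
    return df


def write_contacts(df: pd.DataFrame, path, header: str | None = None) -> None:
    """Write contacts in canonical order; counts use fixed 4-decimal format."""
    df = canonicalize_contacts(df)
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for chrom, bi, bj, count in df.itertuples(index=False):
            fh.write(f"{chrom}\t{bi}\t{bj}\t{_fmt_signal(count)}\n")
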