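"""Synthetic genomes, peak tracks, loops and contact maps.

The generator emulates the statistical structure the pipeline assumes, so
every stage can be exercised without external downloads:

* non-overlapping TADs tiling part of each chromosome,
* per-assay peak tracks in which loop-anchor segments carry peaks with
  elevated presence probability and log-normally distributed heights with a
  shifted log-mean (ChIP-seq signal has a heavy right tail),
* intra-TAD truth loops between anchor segments, planted so that the ratio
  of interacting to non-interacting candidate pairs lands in the 0.01-0.1
  band typical of experimental interaction sets,
* sparse contact maps with Poisson counts around a power-law distance decay,
  multiplicatively boosted at true loops.

Everything is drawn from a single seeded generator in a fixed order, so a
profile plus a seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .errors import ValidationError

FIXTURES = ("ctcf_like", "rnapii_like", "hic_like", "null")


@dataclass(frozen=True)
class AssaySpec:
    """One simulated ChIP-seq track.

    ``p_background`` / ``p_anchor`` are per-segment peak presence
    probabilities away from / at loop anchors; ``mu_*`` are the log-means of
    the log-normal peak-height distribution (``sigma`` is shared).  A role of
    ``mediator`` marks the track used to gate filtration downstream.
    """

    name: str
    role: str = "noise"  # mediator | key_tf | histone | noise
    p_background: float = 0.1
    p_anchor: float = 0.1
    mu_background: float = 1.2
    mu_anchor: float = 1.2
    sigma: float = 0.5

    def __post_init__(self):
        for p in (self.p_background, self.p_anchor):
            if not (0 <= p <= 1):
                raise ValidationError(f"presence probability {p} outside [0, 1]")
        # an anchor-enriched assay must not have a weaker height distribution
        if self.p_anchor > self.p_background and self.mu_anchor < self.mu_background:
            raise ValidationError(
                f"assay {self.name}: anchor height mean below background "
                "for an anchor-enriched assay"
            )


@dataclass
class SimProfile:
    """Full description of one simulated study."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 5_000_000, "chrS2": 5_000_000}
    )
    resolution: int = 1_000
    n_tads: int = 10
    tad_length_range: tuple[int, int] = (400_000, 700_000)
    tad_gap_range: tuple[int, int] = (50_000, 150_000)
    assays: list[AssaySpec] = field(default_factory=list)
    anchors_per_tad: int = 14
    positive_fraction: float = 0.05
    max_loops_per_anchor: int | None = None
    loop_distance_exponent: float = 0.0
    decay_alpha: float = 1.2
    loop_boost: float = 8.0
    count_scale: float = 6.0
    interaction_type: str = "ctcf"  # filtration preset recommended downstream
    name: str = "custom"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.positive_fraction < 0.5):
            raise ValidationError(
                f"positive_fraction must be in (0, 0.5), got {self.positive_fraction}"
            )
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")

    @property
    def mediating_assay(self) -> str | None:
        for a in self.assays:
            if a.role == "mediator":
                return a.name
        return None

    @property
    def enriched_assays(self) -> list[str]:
        return [
            a.name
            for a in self.assays
            if a.p_anchor > a.p_background or a.mu_anchor > a.mu_background
        ]


@dataclass
class SimBundle:
    """In-memory result of one simulation (plus optional on-disk copies)."""

    profile: SimProfile
    chromsizes: dict[str, int]
    tads: list[eio.TadRecord]
    peaks: dict[str, list[eio.PeakRecord]]
    interactions: eio.InteractionSet
    contacts: pd.DataFrame
    anchor_segments: dict[str, np.ndarray]  # chrom -> sorted anchor bin indices

    def all_peaks(self) -> list[eio.PeakRecord]:
        out = []
        for assay in self.peaks:
            out.extend(self.peaks[assay])
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        eio.write_chromsizes(self.chromsizes, out / "chrom.sizes")
        eio.write_bed_tads(self.tads, out / "tads.bed")
        peak_dir = out / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for assay, records in self.peaks.items():
            eio.write_narrowpeak(records, peak_dir / f"{assay}.narrowPeak")
        eio.write_bedpe(self.interactions, out / "interactions.bedpe")
        eio.write_contacts(self.contacts, out / "contacts.tsv")
        meta = asdict(self.profile)
        meta["assays"] = [asdict(a) for a in self.profile.assays]
        with open(out / "profile.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _place_tads(profile: SimProfile, rng: np.random.Generator) -> list[eio.TadRecord]:
    chroms = sorted(profile.chrom_lengths)
    per_chrom = {c: profile.n_tads // len(chroms) for c in chroms}
    for i in range(profile.n_tads % len(chroms)):
        per_chrom[chroms[i]] += 1
    res = profile.resolution
    tads = []
    k = 0
    for chrom in chroms:
        length = profile.chrom_lengths[chrom]
        pos = 0
        for _ in range(per_chrom[chrom]):
            gap = int(rng.integers(*profile.tad_gap_range)) // res * res
            tlen = int(rng.integers(*profile.tad_length_range)) // res * res
            start = pos + gap
            end = start + tlen
            if end > length:
                raise ValidationError(
                    f"cannot place {per_chrom[chrom]} TADs of "
                    f"{profile.tad_length_range} bp on {chrom} ({length} bp)"
                )
            k += 1
            tads.append(eio.TadRecord(chrom, start, end, f"tad_{k:04d}"))
            pos = end
    return tads


def _plan_loops(profile: SimProfile, tads, rng: np.random.Generator):
    """Pick anchor bins and loop pairs per TAD so the realized
    positive:negative ratio targets ``positive_fraction``."""
    res = profile.resolution
    mediator = next((a for a in profile.assays if a.role == "mediator"), None)
    p_bg_med = mediator.p_background if mediator is not None else 1.0
    filtered = profile.interaction_type != "hic_heatmap" and mediator is not None

    anchors: dict[str, set[int]] = {c: set() for c in profile.chrom_lengths}
    loops = []  # (chrom, bin_l, bin_r, tad_id)
    for t in tads:
        b0, b1 = t.start // res, t.end // res
        n_bins = b1 - b0
        pool_size = min(profile.anchors_per_tad, n_bins)
        pool = np.sort(rng.choice(np.arange(b0, b1), size=pool_size, replace=False))
        retained_bg = (n_bins - pool_size) * (p_bg_med if filtered else 1.0)
        exp_retained = pool_size + retained_bg
        exp_pairs = exp_retained * (exp_retained - 1) / 2
        want = max(1, int(round(profile.positive_fraction * exp_pairs
                                / (1 + profile.positive_fraction))))
        cap = profile.max_loops_per_anchor
        max_loops = (
            pool_size * cap // 2 if cap is not None
            else pool_size * (pool_size - 1) // 2
        )
        if want > max_loops:
            feasible = max_loops / max(exp_pairs - max_loops, 1.0)
            raise ValidationError(
                f"positive_fraction {profile.positive_fraction} unreachable in "
                f"{t.tad_id}: needs {want} loops but only {max_loops} anchor "
                f"pairs exist (feasible fraction <= {feasible:.3f}; raise "
                "anchors_per_tad or lower positive_fraction)"
            )
        li, ri = np.triu_indices(pool_size, k=1)
        dist = pool[ri] - pool[li]
        if profile.loop_distance_exponent > 0:
            w = dist.astype(float) ** (-profile.loop_distance_exponent)
            w /= w.sum()
        else:
            w = None
        if cap is None:
            chosen = rng.choice(len(li), size=want, replace=False, p=w)
        else:
            # draw in random (optionally distance-weighted) order, accepting
            # pairs greedily while no anchor exceeds its loop-multiplicity cap
            order = rng.choice(len(li), size=len(li), replace=False, p=w)
            degree = np.zeros(pool_size, dtype=np.int64)
            chosen = []
            for c in order:
                if degree[li[c]] < cap and degree[ri[c]] < cap:
                    degree[li[c]] += 1
                    degree[ri[c]] += 1
                    chosen.append(c)
                    if len(chosen) == want:
                        break
            if len(chosen) < want:
                raise ValidationError(
                    f"could not place {want} loops in {t.tad_id} under "
                    f"max_loops_per_anchor={cap}; lower positive_fraction"
                )
            chosen = np.array(chosen)
        for c in np.sort(chosen):
            loops.append((t.chrom, int(pool[li[c]]), int(pool[ri[c]]), t.tad_id))
        anchors[t.chrom].update(int(b) for b in pool)
    anchor_arr = {c: np.array(sorted(s), dtype=np.int64) for c, s in anchors.items()}
    return anchor_arr, loops


def _simulate_peaks(profile: SimProfile, anchors, rng: np.random.Generator):
    res = profile.resolution
    peaks: dict[str, list[eio.PeakRecord]] = {}
    jitter_max = max(res // 5, 1)
    w_lo, w_hi = max(res // 3, 2), max(2 * res // 3, 3)
    for spec in profile.assays:
        records = []
        for chrom in sorted(profile.chrom_lengths):
            length = profile.chrom_lengths[chrom]
            n = -(-length // res)
            is_anchor = np.zeros(n, dtype=bool)
            if chrom in anchors and len(anchors[chrom]):
                is_anchor[anchors[chrom]] = True
            p = np.where(is_anchor, spec.p_anchor, spec.p_background)
            mu = np.where(is_anchor, spec.mu_anchor, spec.mu_background)
            # fixed-size draws keep the stream identical across profiles
            u = rng.random(n)
            z = rng.normal(size=n)
            jit = rng.integers(-jitter_max, jitter_max + 1, size=n)
            wid = rng.integers(w_lo, w_hi + 1, size=n)
            present = np.where(u < p)[0]
            heights = np.exp(mu + spec.sigma * z)
            for b in present:
                seg_start = int(b) * res
                seg_end = min(seg_start + res, length)
                center = seg_start + (seg_end - seg_start) // 2
                summit = center + int(jit[b])
                start = max(seg_start, summit - int(wid[b]) // 2)
                end = min(seg_end, summit + int(wid[b]) // 2 + 1)
                summit = min(max(summit, start), end - 1)
                records.append(
                    eio.PeakRecord(
                        chrom,
                        start,
                        end,
                        round(float(heights[b]), 4),
                        summit - start,
                        spec.name,
                        name=f"{spec.name}_{chrom}_{b}",
                    )
                )
        peaks[spec.name] = records
    return peaks


def _simulate_contacts(profile: SimProfile, tads, loops, rng: np.random.Generator):
    res = profile.resolution
    loop_set = {(c, i, j) for c, i, j, _ in loops}
    frames = []
    for t in tads:
        b0, b1 = t.start // res, t.end // res
        n = b1 - b0
        if n < 2:
            continue
        li, ri = np.triu_indices(n, k=1)
        bi, bj = li + b0, ri + b0
        d = (ri - li).astype(float)
        mean = profile.count_scale * d ** (-profile.decay_alpha)
        if profile.loop_boost != 1.0 and loop_set:
            is_loop = np.fromiter(
                ((t.chrom, int(i), int(j)) in loop_set for i, j in zip(bi, bj)),
                dtype=bool,
                count=len(bi),
            )
            mean = np.where(is_loop, mean * profile.loop_boost, mean)
        counts = rng.poisson(mean)
        nz = counts > 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t.chrom,
                    "bin_i": bi[nz],
                    "bin_j": bj[nz],
                    "count": counts[nz].astype(float),
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = eio.canonicalize_contacts(df)
    else:
        df = pd.DataFrame(columns=eio.CONTACT_COLUMNS)
    df.attrs["resolution"] = res
    return df


def simulate(profile: SimProfile, out_dir=None) -> SimBundle:
    """Generate a full input bundle from a profile.

    All randomness flows from ``profile.seed`` through one generator in a
    fixed order, so repeated calls (and their written files) are identical.
    """
    rng = np.random.default_rng(profile.seed)
    tads = _place_tads(profile, rng)
    anchors, loops = _plan_loops(profile, tads, rng)
    peaks = _simulate_peaks(profile, anchors, rng)
    contacts = _simulate_contacts(profile, tads, loops, rng)

    res = profile.resolution
    records = []
    for chrom, bl, br, _tad in loops:
        length = profile.chrom_lengths[chrom]
        records.append(
            eio.InteractionRecord(
                chrom,
                bl * res,
                min((bl + 1) * res, length),
                br * res,
                min((br + 1) * res, length),
                score=float(1 + rng.poisson(9)),
            )
        )
    records.sort(
        key=lambda r: (r.chrom, r.left_start, r.left_end, r.right_start, r.right_end)
    )
    interactions = eio.InteractionSet(records=records)

    bundle = SimBundle(
        profile=profile,
        chromsizes=dict(profile.chrom_lengths),
        tads=tads,
        peaks=peaks,
        interactions=interactions,
        contacts=contacts,
        anchor_segments=anchors,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _ctcf_assays() -> list[AssaySpec]:
    assays = [
        AssaySpec("CTCF", "mediator", 0.06, 1.0, 1.5, 2.5, 0.5),
        AssaySpec("SA1", "key_tf", 0.10, 0.9, 1.2, 2.2, 0.5),
        AssaySpec("RAD21", "key_tf", 0.10, 0.9, 1.2, 2.2, 0.5),
        AssaySpec("SMC3", "key_tf", 0.10, 0.9, 1.2, 2.2, 0.5),
        AssaySpec("ZNF143", "key_tf", 0.10, 0.9, 1.2, 2.2, 0.5),
        AssaySpec("RNAPII", "noise", 0.15, 0.15, 1.2, 1.2, 0.5),
        AssaySpec("H3K4me1", "histone", 0.20, 0.20, 1.2, 1.2, 0.5),
        AssaySpec("H3K4me3", "histone", 0.20, 0.20, 1.2, 1.2, 0.5),
        AssaySpec("H3K27ac", "histone", 0.20, 0.20, 1.2, 1.2, 0.5),
        AssaySpec("H3K27me3", "noise", 0.15, 0.15, 1.2, 1.2, 0.5),
        AssaySpec("H3K36me3", "noise", 0.15, 0.15, 1.2, 1.2, 0.5),
    ]
    return assays


def _rnapii_assays() -> list[AssaySpec]:
    return [
        AssaySpec("RNAPII", "mediator", 0.06, 1.0, 1.5, 2.5, 0.5),
        AssaySpec("H3K4me1", "histone", 0.20, 0.95, 1.2, 2.2, 0.5),
        AssaySpec("H3K4me3", "histone", 0.20, 0.95, 1.2, 2.2, 0.5),
        AssaySpec("H3K27ac", "histone", 0.20, 0.95, 1.2, 2.2, 0.5),
        AssaySpec("CTCF", "noise", 0.10, 0.10, 1.2, 1.2, 0.5),
        AssaySpec("SA1", "noise", 0.10, 0.10, 1.2, 1.2, 0.5),
        AssaySpec("RAD21", "noise", 0.10, 0.10, 1.2, 1.2, 0.5),
        AssaySpec("H3K27me3", "noise", 0.15, 0.15, 1.2, 1.2, 0.5),
        AssaySpec("H3K36me3", "noise", 0.15, 0.15, 1.2, 1.2, 0.5),
    ]


def _null_assays() -> list[AssaySpec]:
    """Zero enrichment: anchor and background peak distributions identical."""
    out = []
    for spec in _ctcf_assays():
        out.append(
            AssaySpec(
                spec.name,
                spec.role if spec.role != "mediator" else "noise",
                spec.p_background,
                spec.p_background,
                spec.mu_background,
                spec.mu_background,
                spec.sigma,
            )
        )
    return out


def make_fixture(name: str, seed: int = 0, **overrides) -> SimProfile:
    """Named study profiles.

    * ``ctcf_like`` — CTCF-mediated architectural loops at 1 kb: anchors
      enriched for the {CTCF, SA1, RAD21, SMC3, ZNF143} transcription
      factors, filtration gated by CTCF.
    * ``rnapii_like`` — transcriptional loops at 1 kb: anchors enriched for
      {H3K4me1, H3K4me3, H3K27ac} histone marks, gated by RNAP II.
    * ``hic_like`` — heatmap-style contacts at 5 kb, no filtration, anchors
      enriched for the architectural transcription factors.
    * ``null`` — no anchor enrichment anywhere (5 kb, no filtration); loops
      exist but are statistically invisible in the 1D tracks.

    Keyword overrides replace profile fields (e.g. a smaller genome).
    """
    if name == "ctcf_like":
        prof = SimProfile(assays=_ctcf_assays(), interaction_type="ctcf", name=name)
    elif name == "rnapii_like":
        prof = SimProfile(assays=_rnapii_assays(), interaction_type="rnapii", name=name)
    elif name == "hic_like":
        prof = SimProfile(
            assays=_ctcf_assays(),
            resolution=5_000,
            anchors_per_tad=32,
            interaction_type="hic_heatmap",
            name=name,
        )
    elif name == "null":
        prof = SimProfile(
            assays=_null_assays(),
            resolution=5_000,
            anchors_per_tad=10_000,  # capped at the TAD bin count
            positive_fraction=0.012,
            max_loops_per_anchor=2,
            loop_boost=1.0,
            interaction_type="hic_heatmap",
            name=name,
        )
    else:
        raise ValidationError(f"unknown fixture {name!r}; choose one of {FIXTURES}")
    prof.seed = seed
    return replace(prof, **overrides) if overrides else prof
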