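"""Shared fixtures: small simulated studies and hand-built toy inputs."""

import numpy as np
import pandas as pd
import pytest

from epiloop import binning, synth
from epiloop.io import PeakRecord, TadRecord


@pytest.fixture(scope="session")
def small_ctcf_profile():
    """A reduced architectural-loop study: one 2 Mb chromosome, 3 TADs."""
    return synth.make_fixture(
        "ctcf_like",
        seed=7,
        chrom_lengths={"chrS1": 2_000_000},
        n_tads=3,
        tad_length_range=(300_000, 450_000),
    )


@pytest.fixture(scope="session")
def small_ctcf_bundle(small_ctcf_profile):
    return synth.simulate(small_ctcf_profile)


@pytest.fixture(scope="session")
def small_hic_bundle():
    return synth.simulate(
        synth.make_fixture(
            "hic_like", seed=11, chrom_lengths={"chrS1": 2_000_000},
            n_tads=3, tad_length_range=(300_000, 450_000),
        )
    )


@pytest.fixture()
def toy_segments():
    """Ten 1 kb segments on one 10 kb chromosome."""
    return binning.bin_genome({"chrT": 10_000}, 1_000)


@pytest.fixture()
def toy_table(toy_segments):
    """Feature table over toy_segments with two assays and known peaks."""
    peaks = [
        PeakRecord("chrT", 1_100, 1_600, 5.0, 250, "CTCF"),
        PeakRecord("chrT", 1_200, 1_900, 9.0, 100, "CTCF"),
        PeakRecord("chrT", 8_200, 8_700, 4.0, 300, "H3K4me1"),
    ]
    return binning.assign_peaks(toy_segments, peaks, mode="max",
                                assays=["CTCF", "H3K4me1"])


@pytest.fixture()
def toy_tads():
    return [
        TadRecord("chrT", 0, 5_000, "tadA"),
        TadRecord("chrT", 5_000, 10_000, "tadB"),
    ]


def brute_force_auroc(labels, probabilities):
    """All-pairs rank comparison: P(random positive ranked above random
    negative), ties counting one half."""
    labels = np.asarray(labels)
    probs = np.asarray(probabilities, dtype=float)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    if not len(pos) or not len(neg):
        return float("nan")
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_midrank(counts, value, n_population=None):
    """Midrank percentile of ``value`` in ``counts`` (plus implicit zeros up
    to ``n_population``), enumerated one comparison at a time."""
    counts = list(counts)
    n_pop = n_population if n_population is not None else len(counts)
    counts = counts + [0.0] * (n_pop - len(counts))
    greater = sum(c > value for c in counts)
    equal = sum(c == value for c in counts) - 1  # exclude self
    return (greater + 0.5 * equal) / n_pop


def chi2_closed_form(a, b, c, d):
    """Chi-square of a 2x2 table [[a, b], [c, d]]:
    n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
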