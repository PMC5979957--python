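"""Distance-stratified contact scoring and three-class labeling."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_midrank
from epiloop import heatmap
from epiloop.errors import ValidationError
from epiloop.io import TadRecord


def contacts_df(triples, resolution=1_000, chrom="chrT"):
    df = pd.DataFrame(triples, columns=["bin_i", "bin_j", "count"])
    df.insert(0, "chrom", chrom)
    df["count"] = df["count"].astype(float)
    df.attrs["resolution"] = resolution
    return df


ONE_TAD = [TadRecord("chrT", 0, 10_000, "tadA")]  # bins 0..9 at 1 kb


class TestDistanceScore:
    def test_matches_brute_force_on_three_counts(self):
        # three recorded contacts at distance 2 within a 5-bin TAD would have
        # implicit zeros; use a 5-bin TAD where distance 2 has exactly 3 pairs
        tads = [TadRecord("chrT", 0, 5_000, "t")]
        df = contacts_df([(0, 2, 10), (1, 3, 5), (2, 4, 1)])
        scored = heatmap.distance_score(df, tads=tads)
        by_count = dict(zip(scored["count"], scored["dscore"]))
        assert by_count[10.0] == pytest.approx(brute_force_midrank([10, 5, 1], 10))
        assert by_count[10.0] == pytest.approx(0.0)
        assert by_count[1.0] == pytest.approx(brute_force_midrank([10, 5, 1], 1))
        assert by_count[1.0] == pytest.approx(2 / 3)

    def test_all_equal_counts_score_half(self):
        tads = [TadRecord("chrT", 0, 5_000, "t")]
        df = contacts_df([(0, 2, 7), (1, 3, 7), (2, 4, 7)])
        scored = heatmap.distance_score(df, tads=tads)
        n = 3
        assert np.allclose(scored["dscore"], 0.5 * (n - 1) / n)
        # ties at ~0.5 can never be called interactions at theta=0.15
        states = heatmap.classify_contacts(scored, 0.15)["state"]
        assert (states == heatmap.STATE_NO_CLASS).all()

    def test_unrecorded_pairs_enter_population_as_zeros(self):
        # 10-bin TAD: distance 1 has 9 possible pairs, only one recorded
        df = contacts_df([(0, 1, 5)])
        scored = heatmap.distance_score(df, tads=ONE_TAD)
        assert scored["dscore"].iloc[0] == pytest.approx(
            brute_force_midrank([5], 5, n_population=9)
        )
        assert scored["dscore"].iloc[0] == pytest.approx(0.0)

    def test_recorded_zero_ties_with_implicit_zeros(self):
        df = contacts_df([(0, 1, 0), (3, 4, 2)])
        scored = heatmap.distance_score(df, tads=ONE_TAD)
        zero_row = scored[scored["count"] == 0].iloc[0]
        # population: one 2, eight zeros (7 implicit + this one)
        assert zero_row["dscore"] == pytest.approx(
            brute_force_midrank([0, 2], 0, n_population=9)
        )

    def test_scale_invariance(self):
        df1 = contacts_df([(0, 2, 3), (1, 3, 8), (2, 4, 5), (0, 3, 2), (1, 4, 9)])
        df2 = df1.copy()
        df2["count"] *= 17.0
        df2.attrs["resolution"] = 1_000
        tads = [TadRecord("chrT", 0, 5_000, "t")]
        s1 = heatmap.distance_score(df1, tads=tads)
        s2 = heatmap.distance_score(df2, tads=tads)
        assert np.allclose(s1["dscore"], s2["dscore"])

    def test_monotone_in_count_at_fixed_distance(self):
        rng = np.random.default_rng(5)
        triples = [(i, i + 3, int(c)) for i, c in
                   zip(range(7), rng.integers(0, 50, 7))]
        scored = heatmap.distance_score(contacts_df(triples), tads=ONE_TAD)
        s = scored.sort_values("count")
        assert (np.diff(s["dscore"].to_numpy()) <= 1e-12).all()

    def test_contact_spanning_two_tads_dropped(self):
        tads = [TadRecord("chrT", 0, 5_000, "a"), TadRecord("chrT", 5_000, 10_000, "b")]
        df = contacts_df([(2, 7, 4), (1, 3, 4)])
        scored = heatmap.distance_score(df, tads=tads)
        assert len(scored) == 1
        assert scored["stratum"].iloc[0] == "a"

    def test_chromosome_stratum_with_sizes(self):
        df = contacts_df([(0, 1, 5), (3, 4, 1)])
        scored = heatmap.distance_score(
            df, stratum="chromosome", chromsizes={"chrT": 10_000}
        )
        # population at distance 1 is 9 pairs; counts {5, 1} + 7 zeros
        assert scored[scored["count"] == 5]["dscore"].iloc[0] == pytest.approx(0.0)
        assert scored[scored["count"] == 1]["dscore"].iloc[0] == pytest.approx(
            brute_force_midrank([5, 1], 1, n_population=9)
        )

    def test_missing_resolution_rejected(self):
        df = contacts_df([(0, 1, 5)])
        df.attrs.pop("resolution")
        with pytest.raises(ValidationError):
            heatmap.distance_score(df, tads=ONE_TAD)


class TestClassify:
    @pytest.mark.parametrize(
        "dscore,theta,state",
        [
            (0.10, 0.15, heatmap.STATE_INTERACTION),
            (0.15, 0.15, heatmap.STATE_INTERACTION),  # boundary inclusive
            (0.90, 0.15, heatmap.STATE_NON_INTERACTION),
            (0.85, 0.15, heatmap.STATE_NON_INTERACTION),
            (0.50, 0.15, heatmap.STATE_NO_CLASS),
            (0.16, 0.15, heatmap.STATE_NO_CLASS),
        ],
    )
    def test_three_class_semantics(self, dscore, theta, state):
        scored = contacts_df([(0, 1, 1)])
        scored["dscore"] = dscore
        assert heatmap.classify_contacts(scored, theta)["state"].iloc[0] == state

    def test_theta_half_empties_no_class(self):
        rng = np.random.default_rng(1)
        scored = contacts_df([(i, i + 1, 1) for i in range(20)])
        scored["dscore"] = rng.uniform(0, 1, 20)
        states = heatmap.classify_contacts(scored, 0.5)["state"]
        assert (states != heatmap.STATE_NO_CLASS).all()

    @pytest.mark.parametrize("theta", [0.0, -0.1, 0.6, 1.0])
    def test_invalid_theta_rejected(self, theta):
        scored = contacts_df([(0, 1, 1)])
        scored["dscore"] = 0.5
        with pytest.raises(ValidationError):
            heatmap.classify_contacts(scored, theta)

    def test_interaction_fraction_tracks_theta(self):
        """With all-distinct counts the per-stratum interaction fraction is
        within 1/N_d of theta at every distance."""
        rng = np.random.default_rng(9)
        n_bins, theta = 30, 0.15
        tads = [TadRecord("chrT", 0, n_bins * 1_000, "t")]
        triples = []
        counts = iter(rng.permutation(10_000)[: n_bins * n_bins].tolist())
        for d in range(1, n_bins):
            for i in range(n_bins - d):
                triples.append((i, i + d, 1 + next(counts)))
        classified = heatmap.classify_contacts(
            heatmap.distance_score(contacts_df(triples), tads=tads), theta
        )
        for d, grp in classified.groupby("distance_bins"):
            n_d = len(grp)
            frac = (grp["state"] == heatmap.STATE_INTERACTION).mean()
            assert abs(frac - theta) <= 1 / n_d + 1e-12


class TestContactsToPairs:
    @pytest.fixture()
    def table(self):
        from epiloop import binning

        return binning.assign_peaks(
            binning.bin_genome({"chrT": 10_000}, 1_000), [], assays=["CTCF"]
        )

    PAIRS = [(0, 2), (1, 3), (2, 4), (3, 5), (4, 6),
             (5, 7), (6, 8), (7, 9), (0, 5), (1, 6)]

    def _classified(self, dscores):
        df = contacts_df([(i, j, 1) for i, j in self.PAIRS[: len(dscores)]])
        scored = heatmap.distance_score(df, tads=ONE_TAD)
        assert len(scored) == len(dscores)
        scored["dscore"] = dscores  # overwrite for a controlled state mix
        return heatmap.classify_contacts(scored, 0.15)

    def test_counts_and_no_class_exclusion(self, table):
        classified = self._classified(
            [0.05, 0.1, 0.12, 0.9, 0.92, 0.95, 0.99, 1.0, 0.4, 0.6]
        )
        pairs = heatmap.contacts_to_pairs(classified, table, ONE_TAD)
        assert len(pairs) == 8  # 3 interactions + 5 non-interactions
        assert pairs["label"].sum() == 3
        assert "pair_max_CTCF_height" in pairs.columns

    def test_theta_half_labels_every_contact(self, table):
        df = contacts_df([(0, 2, 9), (1, 3, 4), (0, 4, 2)])
        classified = heatmap.classify_contacts(
            heatmap.distance_score(df, tads=ONE_TAD), 0.5
        )
        pairs = heatmap.contacts_to_pairs(classified, table, ONE_TAD)
        assert len(pairs) == 3

    def test_empty_input(self, table):
        classified = self._classified([0.4, 0.5])  # all no-class
        pairs = heatmap.contacts_to_pairs(classified, table, ONE_TAD)
        assert len(pairs) == 0

    def test_bin_beyond_table_is_integrity_error(self, table):
        from epiloop.errors import IntegrityError

        classified = self._classified([0.05])
        classified.loc[0, "bin_j"] = 99
        with pytest.raises(IntegrityError):
            heatmap.contacts_to_pairs(classified, table, ONE_TAD)
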