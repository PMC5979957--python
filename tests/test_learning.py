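"""Splitting, training, prediction, metrics and feature reporting."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_auroc, chi2_closed_form
from epiloop import learning
from epiloop.errors import IntegrityError, ValidationError
from epiloop.learning import SplitSpec


def make_pairs(n=100, seed=0, separation=0.0, n_tads=5, n_chroms=2):
    """Labeled pair table with optional feature separation between classes."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < 0.3).astype(np.int8)
    base = rng.normal(5, 1, (n, 2))
    base[labels == 1] += separation
    df = pd.DataFrame(
        {
            "tad_id": [f"t{i % n_tads}" for i in range(n)],
            "chrom": [f"chr{i % n_chroms}" for i in range(n)],
            "pair_min_A_height": np.minimum(base[:, 0], base[:, 1]).clip(0),
            "pair_max_A_height": np.maximum(base[:, 0], base[:, 1]).clip(0),
            "pair_min_A_summitdist": rng.uniform(0, 1000, n),
            "pair_max_A_summitdist": rng.uniform(0, 1000, n),
            "genomic_distance": rng.integers(1_000, 500_000, n),
            "left_order": rng.integers(0, 20, n),
            "right_order": rng.integers(20, 40, n),
            "label": labels,
        }
    )
    return df


class TestSplit:
    def test_80_20_disjoint_exhaustive(self):
        pairs = make_pairs(100)
        train, test = learning.split(pairs, SplitSpec(seed=3))
        assert len(train) == 80 and len(test) == 20

    def test_same_seed_same_partition(self):
        pairs = make_pairs(97)
        t1 = learning.split(pairs, SplitSpec(seed=5))
        t2 = learning.split(pairs, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(t1[0], t2[0])
        pd.testing.assert_frame_equal(t1[1], t2[1])
        t3 = learning.split(pairs, SplitSpec(seed=6))
        assert not t3[0].equals(t1[0])

    @pytest.mark.parametrize("level,key", [("tad", "tad_id"), ("chromosome", "chrom")])
    def test_group_levels_keep_groups_whole(self, level, key):
        pairs = make_pairs(120, n_tads=6, n_chroms=3)
        train, test = learning.split(pairs, SplitSpec(seed=1, level=level))
        assert set(train[key]) & set(test[key]) == set()
        assert len(train) + len(test) == 120

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValidationError):
            learning.split(make_pairs(1), SplitSpec())
        with pytest.raises(ValidationError):
            learning.SplitSpec(train_fraction=1.0)


class TestTrainPredict:
    def test_separable_data_high_auroc(self):
        pairs = make_pairs(400, separation=5.0)
        train, test = learning.split(pairs, SplitSpec(seed=0))
        model = learning.train(train, hyperparams={"n_estimators": 100}, seed=0)
        probs = learning.predict(model, test)
        rep = learning.evaluate(test, probs)
        assert rep.auroc >= 0.95

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        pairs = make_pairs(400, separation=5.0, seed=2)
        pairs["label"] = rng.permutation(pairs["label"].to_numpy())
        train, test = learning.split(pairs, SplitSpec(seed=2))
        model = learning.train(train, hyperparams={"n_estimators": 100}, seed=2)
        rep = learning.evaluate(test, learning.predict(model, test))
        assert 0.3 <= rep.auroc <= 0.7

    def test_single_class_training_rejected(self):
        pairs = make_pairs(50)
        pairs["label"] = 0
        with pytest.raises(ValidationError, match="positive"):
            learning.train(pairs)

    def test_missing_feature_column_is_integrity_error(self):
        pairs = make_pairs(60, separation=3.0)
        model = learning.train(pairs, hyperparams={"n_estimators": 20})
        with pytest.raises(IntegrityError, match="pair_min_A_height"):
            learning.predict(model, pairs.drop(columns=["pair_min_A_height"]))

    def test_feature_column_order_irrelevant(self):
        pairs = make_pairs(80, separation=3.0)
        model = learning.train(pairs, hyperparams={"n_estimators": 50})
        p1 = learning.predict(model, pairs)
        p2 = learning.predict(model, pairs[pairs.columns[::-1]])
        assert np.array_equal(p1, p2)

    def test_empty_pairs_empty_output(self):
        pairs = make_pairs(60, separation=3.0)
        model = learning.train(pairs, hyperparams={"n_estimators": 20})
        assert len(learning.predict(model, pairs.iloc[:0])) == 0

    def test_exclude_distance_drops_feature(self):
        pairs = make_pairs(60, separation=3.0)
        model = learning.train(
            pairs, hyperparams={"n_estimators": 20}, include_distance=False
        )
        assert "genomic_distance" not in model.feature_names
        assert "left_order" in model.feature_names

    @pytest.mark.parametrize("kind", ["adaboost", "gbm"])
    def test_alternative_classifiers_plug_in(self, kind):
        pairs = make_pairs(200, separation=5.0)
        train, test = learning.split(pairs, SplitSpec(seed=0))
        model = learning.train(train, classifier_kind=kind, seed=0)
        rep = learning.evaluate(test, learning.predict(model, test))
        assert rep.auroc >= 0.9

    def test_class_balance_modes_run(self):
        pairs = make_pairs(300, separation=4.0)
        for mode in ("downsample", "weight"):
            model = learning.train(
                pairs, hyperparams={"n_estimators": 30}, class_balance=mode
            )
            assert len(learning.predict(model, pairs)) == len(pairs)

    def test_cross_dataset_fills_missing_with_sentinel(self):
        pairs = make_pairs(60, separation=3.0)
        model = learning.train(pairs, hyperparams={"n_estimators": 20})
        reduced = pairs.drop(columns=["pair_min_A_summitdist"])
        probs = learning.predict_cross_dataset(model, reduced, resolution=1_000)
        assert len(probs) == len(pairs)


class TestEvaluate:
    def test_confusion_metric_identities(self):
        # TP=8, FN=2, TN=85, FP=5
        labels = np.array([1] * 10 + [0] * 90, dtype=np.int8)
        probs = np.concatenate([
            np.full(8, 0.9), np.full(2, 0.1),   # positives: 8 called, 2 missed
            np.full(5, 0.9), np.full(85, 0.1),  # negatives: 5 false alarms
        ])
        pairs = make_pairs(100)
        pairs["label"] = labels
        rep = learning.evaluate(pairs, probs)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (8, 2, 5, 85)
        assert rep.sensitivity == pytest.approx(0.800)
        assert rep.specificity == pytest.approx(85 / 90, abs=5e-4)
        assert rep.accuracy == pytest.approx(0.930)

    def test_perfect_ranking_auroc_one(self):
        pairs = make_pairs(40)
        pairs["label"] = np.array([1] * 10 + [0] * 30, dtype=np.int8)
        probs = np.concatenate([np.linspace(0.6, 1, 10), np.linspace(0, 0.5, 30)])
        assert learning.evaluate(pairs, probs).auroc == 1.0

    def test_four_pair_toy_matches_rank_oracle(self):
        pairs = make_pairs(4)
        pairs["label"] = np.array([1, 1, 0, 0], dtype=np.int8)
        probs = np.array([0.9, 0.4, 0.6, 0.2])
        rep = learning.evaluate(pairs, probs)
        assert rep.auroc == pytest.approx(0.75)
        assert rep.auroc == pytest.approx(brute_force_auroc(pairs["label"], probs))

    def test_auroc_equals_brute_force_on_random_toys(self):
        rng = np.random.default_rng(11)
        for n in (20, 77, 200):
            pairs = make_pairs(n, seed=n)
            probs = rng.choice(np.round(np.linspace(0, 1, 11), 2), n)
            if pairs["label"].nunique() < 2:
                continue
            rep = learning.evaluate(pairs, probs)
            assert rep.auroc == pytest.approx(
                brute_force_auroc(pairs["label"], probs)
            )

    def test_coverage_requires_table(self):
        pairs = make_pairs(10)
        with pytest.raises(ValidationError):
            learning.evaluate(pairs, np.zeros(10), truth_interactions=[])


class TestSerialization:
    def test_save_load_bit_identical_predictions(self, tmp_path):
        pairs = make_pairs(150, separation=3.0)
        train, test = learning.split(pairs, SplitSpec(seed=4))
        model = learning.train(train, hyperparams={"n_estimators": 60}, seed=4)
        before = learning.predict(model, test)
        path = tmp_path / "model.joblib"
        learning.save_model(model, path)
        reloaded = learning.load_model(path)
        after = learning.predict(reloaded, test)
        assert np.array_equal(before, after)
        assert reloaded.config_hash() == model.config_hash()


class TestFeatureReport:
    def test_chi_square_matches_closed_form(self):
        stat, p, low = learning.chi_square_presence(
            np.array([1.0] * 40 + [0.0] * 40),
            np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30),
        )
        assert stat == pytest.approx(chi2_closed_form(30, 10, 10, 30))
        assert stat == pytest.approx(20.0)
        assert not low

    def test_independent_feature_chi_square_zero(self):
        stat, p, _ = learning.chi_square_presence(
            np.array([1.0, 1.0, 0.0, 0.0] * 10),
            np.array([1, 0, 1, 0] * 10),
        )
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_low_expected_cell_flagged_not_suppressed(self):
        stat, p, low = learning.chi_square_presence(
            np.array([1.0] * 3 + [0.0] * 17),
            np.array([1] * 2 + [0] * 18),
        )
        assert low
        assert np.isfinite(stat)

    def test_report_ranks_informative_assay_first(self):
        rng = np.random.default_rng(0)
        n = 400
        labels = (rng.random(n) < 0.3).astype(np.int8)
        df = pd.DataFrame(
            {
                "pair_min_SIG_height": labels * rng.uniform(4, 6, n),
                "pair_max_SIG_height": labels * rng.uniform(6, 8, n),
                "pair_min_SIG_summitdist": rng.uniform(0, 1000, n),
                "pair_max_SIG_summitdist": rng.uniform(0, 1000, n),
                "pair_min_BG_height": rng.uniform(0, 5, n),
                "pair_max_BG_height": rng.uniform(5, 10, n),
                "pair_min_BG_summitdist": rng.uniform(0, 1000, n),
                "pair_max_BG_summitdist": rng.uniform(0, 1000, n),
                "genomic_distance": rng.integers(1_000, 500_000, n),
                "left_order": rng.integers(0, 20, n),
                "right_order": rng.integers(20, 40, n),
                "label": labels,
            }
        )
        model = learning.train(df, hyperparams={"n_estimators": 100})
        rep = learning.feature_report(model, df)
        assert rep.assays["assay"].iloc[0] == "SIG"
        # signal pairs accumulate more summed anchor height than background
        sig = rep.assays.set_index("assay").loc["SIG"]
        assert sig["signal_mean"] > sig["background_mean"]
        top = rep.features.iloc[0]
        assert top["feature"].endswith("SIG_height")
        assert top["p_value"] < 1e-6
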