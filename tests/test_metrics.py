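"""Accuracy, AUC, R^2, confusion matrices, RFE and the linear baseline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutstab.datasets import LabeledDataset
from mutstab.metrics import (
    accuracy,
    baseline_single_feature,
    confusion,
    r_squared,
    rfe_rank,
    roc_auc,
    roc_points,
)
from mutstab.model import ModelSpec
from mutstab import synth


def auc_by_pair_counting(scores, labels):
    """Brute-force oracle: P(stable outscores unstable), ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == "stable"]
    neg = [s for s, l in zip(scores, labels) if l == "unstable"]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAccuracyAndR2:
    def test_identical_labels(self):
        assert accuracy(["stable", "unstable"], ["stable", "unstable"]) == 1.0

    def test_partial_agreement(self):
        assert accuracy([1, 1, 2, 2], [1, 2, 2, 2]) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy([1], [1, 2])

    def test_affine_invariance(self):
        obs = np.array([0.3, -1.2, 2.2, 0.0, 5.1])
        assert r_squared(2 * obs + 3, obs) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        # r = 8 / (sqrt(10) * sqrt(10)) = 0.8 by hand, so R^2 = 0.64
        assert r_squared([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.64)


class TestRocAuc:
    def test_perfect_separation(self):
        labels = ["unstable"] * 5 + ["stable"] * 5
        scores = list(range(10))
        assert roc_auc(scores, labels) == 1.0

    def test_sign_reversal_reflects(self):
        rng = np.random.default_rng(1)
        labels = ["stable" if b else "unstable" for b in rng.random(40) < 0.4]
        scores = rng.normal(size=40)
        assert roc_auc(-scores, labels) == pytest.approx(1 - roc_auc(scores, labels))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        labels = ["stable" if b else "unstable" for b in rng.random(4000) < 0.5]
        assert roc_auc(rng.normal(size=4000), labels) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], ["stable", "stable"])

    @given(data=st.data(), n=st.integers(4, 20))
    @settings(derandomize=True, max_examples=60)
    def test_matches_pairwise_probability_oracle(self, data, n):
        labels = data.draw(
            st.lists(st.sampled_from(["stable", "unstable"]), min_size=n, max_size=n)
        )
        if len(set(labels)) < 2:
            labels[0], labels[1] = "stable", "unstable"
        scores = data.draw(
            st.lists(
                st.integers(-3, 3).map(float), min_size=n, max_size=n
            )  # small range forces ties
        )
        assert roc_auc(scores, labels) == pytest.approx(
            auc_by_pair_counting(scores, labels)
        )

    @given(seed=st.integers(0, 50))
    @settings(derandomize=True, max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["stable" if b else "unstable" for b in rng.random(30) < 0.4]
        if len(set(labels)) < 2:
            labels[:2] = ["stable", "unstable"]
        scores = rng.normal(size=30)
        assert roc_auc(np.exp(scores) + 5, labels) == pytest.approx(
            roc_auc(scores, labels)
        )

    def test_curve_points_start_and_end(self):
        labels = ["unstable", "stable", "unstable", "stable"]
        pts = roc_points([0.1, 0.9, 0.4, 0.8], labels)
        assert pts.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert pts.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]


class TestConfusion:
    def test_row_sums_are_class_counts(self):
        true = ["stable", "stable", "neutral", "unstable", "unstable", "unstable"]
        pred = ["stable", "neutral", "neutral", "unstable", "stable", "unstable"]
        mat = confusion(pred, true)
        assert mat.loc["stable"].sum() == 2
        assert mat.loc["neutral"].sum() == 1
        assert mat.loc["unstable"].sum() == 3
        assert mat.to_numpy().sum() == len(true)


class TestRfe:
    def test_planted_signal_ranks_first(self):
        ds = synth.generate_dataset(
            task="regression", n=250, n_proteins=8, noise_sd=0.3, seed=3,
            effect={"rosetta_ddg": 1.0},
        )
        ranks = rfe_rank(
            ds, ModelSpec("random_forest", "regression", seed=0), n_resamples=3
        )
        assert ranks["rosetta_ddg"] == 1
        assert sorted(ranks.values()) == list(range(1, 10))

    def test_duplicated_uninformative_features_eliminated_together(self):
        # a pair of byte-identical noise columns ties in drop-one importance
        # and is eliminated first, in adjacent rounds
        rng = np.random.default_rng(4)
        ds = synth.generate_dataset(
            task="regression", n=200, n_proteins=8, noise_sd=0.2, seed=4,
            effect={"rosetta_ddg": 1.0, "ASA_pct": 0.03, "delta_Hydro": 0.2,
                    "delta_SASA": 0.02, "delta_Chg": 0.5, "delta_ARM": 0.8,
                    "SecSt": 0.4},
        )
        X = ds.X.copy()
        noise = rng.normal(size=len(ds))
        X["delta_MW"] = noise
        X["delta_VdwV"] = noise
        dup = LabeledDataset(
            X=X, y=ds.y, labels=ds.labels, proteins=ds.proteins,
            direction=ds.direction, task="regression", target_name="ddg",
        )
        ranks = rfe_rank(dup, ModelSpec("pls", "regression", seed=0))
        assert {ranks["delta_MW"], ranks["delta_VdwV"]} == {8, 9}

    def test_drop_one_importance_path(self):
        ds = synth.generate_dataset(
            task="binary", n=150, n_proteins=8, noise_sd=0.3, seed=5,
            effect={"rosetta_ddg": 1.0},
        )
        ranks = rfe_rank(ds, ModelSpec("naive_bayes", "binary", seed=0))
        assert ranks["rosetta_ddg"] <= 2


class TestBaseline:
    def test_feature_equal_to_target_gives_one(self, planted_regression):
        ds = planted_regression
        X = ds.X.copy()
        X["rosetta_ddg"] = ds.y.to_numpy()
        perfect = LabeledDataset(
            X=X, y=ds.y, labels=ds.labels, proteins=ds.proteins,
            direction=ds.direction, task="regression", target_name="ddg",
        )
        assert baseline_single_feature(perfect, "rosetta_ddg", seed=0) == pytest.approx(
            1.0
        )

    def test_pure_noise_feature_near_zero(self, planted_regression):
        ds = planted_regression
        rng = np.random.default_rng(0)
        X = ds.X.copy()
        X["delta_ARM"] = rng.normal(size=len(ds))
        noisy = LabeledDataset(
            X=X, y=ds.y, labels=ds.labels, proteins=ds.proteins,
            direction=ds.direction, task="regression", target_name="ddg",
        )
        vals = [baseline_single_feature(noisy, "delta_ARM", seed=s) for s in range(5)]
        assert np.mean(vals) < 0.08

    def test_zero_variance_feature_rejected(self, planted_regression):
        ds = planted_regression
        X = ds.X.copy()
        X["delta_Chg"] = 0.0
        flat = LabeledDataset(
            X=X, y=ds.y, labels=ds.labels, proteins=ds.proteins,
            direction=ds.direction, task="regression", target_name="ddg",
        )
        with pytest.raises(ValueError, match="zero variance"):
            baseline_single_feature(flat, "delta_Chg", seed=0)

    def test_unknown_feature_rejected(self, planted_regression):
        with pytest.raises(ValueError):
            baseline_single_feature(planted_regression, "nope", seed=0)
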