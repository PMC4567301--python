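"""Splitting, training, cross-validation and the Model/Results objects."""

import numpy as np
import pandas as pd
import pytest

from mutstab.datasets import LabeledDataset
from mutstab.model import (
    ModelSpec,
    SplitScheme,
    StabilityModel,
    _check_columns,
    cross_validate,
    predict,
    r_squared,
    split,
    train,
)
from mutstab import synth


def _nrows(n, frac):
    return int(round(frac * n))


class TestSplit:
    def test_random_row_sizes(self, planted_regression):
        ds = planted_regression
        train_ds, test_ds = split(ds, SplitScheme("random_row", 0.8, seed=1))
        assert len(train_ds) == _nrows(len(ds), 0.8)
        assert len(train_ds) + len(test_ds) == len(ds)

    def test_same_seed_same_split(self, planted_regression):
        a = split(planted_regression, SplitScheme(seed=5))
        b = split(planted_regression, SplitScheme(seed=5))
        pd.testing.assert_frame_equal(a[0].X, b[0].X)
        pd.testing.assert_frame_equal(a[1].X, b[1].X)

    def test_different_seed_different_split(self, planted_regression):
        a = split(planted_regression, SplitScheme(seed=5))
        b = split(planted_regression, SplitScheme(seed=6))
        assert not a[0].X.equals(b[0].X)

    def test_by_protein_disjoint(self, planted_regression):
        train_ds, test_ds = split(
            planted_regression, SplitScheme("by_protein", 0.8, seed=2)
        )
        assert not (set(train_ds.proteins) & set(test_ds.proteins))
        assert len(train_ds) + len(test_ds) == len(planted_regression)

    def test_by_protein_reaches_train_fraction(self, planted_regression):
        train_ds, _ = split(planted_regression, SplitScheme("by_protein", 0.8, seed=2))
        assert len(train_ds) >= 0.8 * len(planted_regression)

    def test_by_protein_single_protein_errors(self, planted_regression):
        one = planted_regression.subset(
            np.flatnonzero(planted_regression.proteins == planted_regression.proteins[0])
        )
        with pytest.raises(ValueError):
            split(one, SplitScheme("by_protein", 0.8, seed=0))


class TestTrain:
    def test_separable_data_memorized_by_svm(self, planted_binary):
        # a strong planted signal with a wide class gap is nearly separable
        spec = ModelSpec("svm_rbf", "binary", seed=0, cv_folds=5)
        fitted = train(planted_binary, spec)
        preds = predict(fitted, planted_binary)
        assert np.mean(preds.labels == planted_binary.labels.to_numpy()) > 0.95

    def test_knn_k1_memorizes_training_set(self, planted_binary):
        spec = ModelSpec(
            "knn", "binary", grid={"est__n_neighbors": [1]}, seed=0, cv_folds=5
        )
        fitted = train(planted_binary, spec)
        preds = predict(fitted, planted_binary)
        assert np.mean(preds.labels == planted_binary.labels.to_numpy()) == 1.0

    def test_constant_target_r2_is_zero_with_warning(self, planted_regression):
        ds = planted_regression
        const = LabeledDataset(
            X=ds.X, y=pd.Series(np.ones(len(ds))), labels=ds.labels,
            proteins=ds.proteins, direction=ds.direction,
            task="regression", target_name="ddg",
        )
        spec = ModelSpec("knn", "regression", seed=0, cv_folds=5)
        fitted = train(const, spec)
        preds = predict(fitted, const)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert r_squared(preds.values, const.y.to_numpy()) == 0.0

    def test_zero_variance_feature_warns(self, planted_binary):
        ds = planted_binary
        X = ds.X.copy()
        X["delta_Chg"] = 0.0
        degenerate = LabeledDataset(
            X=X, y=ds.y, labels=ds.labels, proteins=ds.proteins,
            direction=ds.direction, task="binary", target_name="ddg",
        )
        with pytest.warns(UserWarning, match="delta_Chg"):
            train(degenerate, ModelSpec("naive_bayes", "binary", seed=0, cv_folds=5))

    def test_fewer_rows_than_folds_errors(self, planted_binary):
        tiny = planted_binary.subset(np.arange(6))
        with pytest.raises(ValueError, match="fewer"):
            train(tiny, ModelSpec("naive_bayes", "binary", seed=0, cv_folds=10))

    def test_naive_bayes_rejected_for_regression(self):
        with pytest.raises(ValueError):
            ModelSpec("naive_bayes", "regression")


class TestCrossValidate:
    def test_label_noise_gives_majority_prior(self, planted_binary):
        rng = np.random.default_rng(0)
        ds = planted_binary
        shuffled = LabeledDataset(
            X=ds.X,
            y=ds.y,
            labels=pd.Series(rng.permutation(ds.labels.to_numpy())),
            proteins=ds.proteins,
            direction=ds.direction,
            task="binary",
            target_name="ddg",
        )
        prior = max(shuffled.class_counts().values()) / len(shuffled)
        spec = ModelSpec("naive_bayes", "binary", seed=0, cv_folds=5)
        cv = cross_validate(shuffled, spec)
        assert cv == pytest.approx(prior, abs=0.10)

    def test_noiseless_linear_pls_r2_is_one(self):
        ds = synth.generate_dataset(
            task="regression", n=200, n_proteins=8, noise_sd=0.0, seed=5,
            effect={"rosetta_ddg": 1.0, "delta_Hydro": 0.2},
        )
        spec = ModelSpec("pls", "regression", seed=0, cv_folds=5)
        assert cross_validate(ds, spec) == pytest.approx(1.0, abs=1e-3)

    def test_seeded_reproducibility(self, planted_binary):
        spec = ModelSpec("svm_rbf", "binary", seed=3, cv_folds=5)
        assert cross_validate(planted_binary, spec) == cross_validate(
            planted_binary, spec
        )


class TestPredict:
    def test_scores_finite_and_labelled(self, planted_binary):
        spec = ModelSpec("random_forest", "binary", seed=0, cv_folds=5,
                         grid={"est__max_features": [3]})
        fitted = train(planted_binary, spec)
        preds = predict(fitted, planted_binary)
        assert np.all(np.isfinite(preds.scores))
        assert set(preds.labels) <= {"stable", "unstable"}

    def test_column_mismatch_detected(self, planted_binary):
        bad = planted_binary.X.rename(columns={"SecSt": "secondary"})
        with pytest.raises(ValueError, match="SecSt"):
            _check_columns(bad)


class TestNoLeakage:
    def test_perturbing_test_rows_leaves_model_unchanged(self):
        ds = synth.generate_dataset(
            task="binary", n=200, n_proteins=8, noise_sd=0.5, seed=9
        )
        scheme = SplitScheme("random_row", 0.8, seed=4)
        # identify the held-out rows exactly as split() will
        rng = np.random.default_rng(scheme.seed)
        order = rng.permutation(len(ds))
        test_rows = np.sort(order[int(round(0.8 * len(ds))):])

        frame = ds.to_frame()
        frame.loc[test_rows, "rosetta_ddg"] += 1000.0
        perturbed = LabeledDataset.from_frame(frame, "binary", "ddg")

        res_a = StabilityModel(ds, "naive_bayes", cv_folds=5, seed=4).fit()
        res_b = StabilityModel(perturbed, "naive_bayes", cv_folds=5, seed=4).fit()
        probe = ds.X.to_numpy(dtype=float)[:25]
        np.testing.assert_array_equal(
            res_a.fitted.pipeline.predict(probe), res_b.fitted.pipeline.predict(probe)
        )
        assert res_a.cv_metric == res_b.cv_metric


class TestParameterRecovery:
    def test_pls_recovers_coefficient_signs_and_ordering(self):
        effect = {"rosetta_ddg": 1.0, "ASA_pct": 0.02, "delta_Hydro": 0.1}
        ds = synth.generate_dataset(
            task="regression", n=400, n_proteins=10, noise_sd=0.05, seed=2,
            effect=effect,
        )
        spec = ModelSpec("pls", "regression", seed=0, cv_folds=5)
        fitted = train(ds, spec)
        coefs = dict(
            zip(fitted.feature_columns, np.ravel(fitted.pipeline["est"].coef_))
        )
        # standardized coefficients: planted effects are all positive and
        # rosetta carries by far the largest variance contribution
        assert coefs["rosetta_ddg"] > 0
        assert coefs["ASA_pct"] > 0
        assert coefs["delta_Hydro"] > 0
        assert coefs["rosetta_ddg"] > abs(coefs["ASA_pct"])
        assert coefs["rosetta_ddg"] > abs(coefs["delta_Hydro"])


class TestStabilityModelResults:
    def test_summary_and_report(self, planted_binary):
        res = StabilityModel(planted_binary, "naive_bayes", cv_folds=5, seed=1).fit()
        text = res.summary()
        assert "naive_bayes" in text and "CV accuracy" in text
        report = res.report.to_dict()
        assert 0 <= report["test_accuracy"] <= 1
        assert 0 <= report["test_auc"] <= 1
        # confusion row sums equal observed class counts on the test side
        row_sums = res.confusion.sum(axis=1).to_dict()
        assert row_sums == res.test_ds.class_counts()

    def test_identical_config_identical_reports(self, planted_binary):
        a = StabilityModel(planted_binary, "naive_bayes", cv_folds=5, seed=2).fit()
        b = StabilityModel(planted_binary, "naive_bayes", cv_folds=5, seed=2).fit()
        assert a.report.to_dict() == b.report.to_dict()


class TestSerialization:
    def test_save_load_roundtrip_with_manifest(self, planted_binary, tmp_path):
        import json

        from mutstab.model import FittedModel, ModelSpec, train, predict

        spec = ModelSpec("naive_bayes", "binary", seed=0, cv_folds=5)
        fitted = train(planted_binary, spec)
        path = tmp_path / "model.pkl"
        fitted.save(path)
        manifest = json.loads((tmp_path / "model.pkl.manifest.json").read_text())
        assert manifest["feature_columns"][-1] == "rosetta_ddg"
        assert len(manifest["standardization"]["mean"]) == 9
        assert manifest["dataset_hash"]
        back = FittedModel.load(path)
        a = predict(fitted, planted_binary)
        b = predict(back, planted_binary)
        np.testing.assert_array_equal(a.labels, b.labels)
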