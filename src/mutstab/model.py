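"""Model fitting: splits, the six learner families, tuning and CV.

The entry point is :class:`StabilityModel`, which is constructed from a
:class:`~mutstab.datasets.LabeledDataset` plus an algorithm name and
whose :meth:`~StabilityModel.fit` returns a :class:`StabilityResults`
carrying the cross-validation metric, held-out test metrics, the
confusion matrix and a ``summary()`` table.  The lower-level pieces —
:func:`split`, :func:`train`, :func:`cross_validate`, :func:`predict` —
are usable on their own.

Six learner families are supported: RBF-kernel SVM, random forest,
Gaussian naive Bayes (classification only), K nearest neighbors, a
single-hidden-layer neural network, and partial least squares (PLS-DA
with one-hot targets and argmax decoding for classification).
Hyperparameters are tuned by grid search scored with seeded k-fold CV
(accuracy for classification, RMSE for regression); features are
standardized inside the pipeline so scaling parameters are learned from
training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .augment import augment_dataset
from .datasets import LabeledDataset
from .features import FEATURE_COLUMNS

ALGORITHMS = ("svm_rbf", "random_forest", "naive_bayes", "knn", "neural_net", "pls")

#: positive class used for ROC scores in binary tasks
POSITIVE_CLASS = "stable"


# ---------------------------------------------------------------------------
# Splitting

@dataclass(frozen=True)
class SplitScheme:
    """Train/test split description.

    ``random_row`` samples rows; ``by_protein`` samples whole proteins
    until the training side first reaches ``train_fraction`` of rows, so
    no protein (hence no residue position) spans both sides.
    """

    kind: str = "random_row"
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_row", "by_protein"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split(ds: LabeledDataset, scheme: SplitScheme) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic seeded train/test split."""
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "random_row":
        order = rng.permutation(n)
        n_train = int(round(scheme.train_fraction * n))
        train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    else:
        proteins = sorted(ds.proteins.unique())
        if len(proteins) < 2:
            raise ValueError("by_protein split needs at least two proteins")
        order = rng.permutation(len(proteins))
        target_rows = scheme.train_fraction * n
        counts = ds.proteins.value_counts()
        train_proteins: set[str] = set()
        rows = 0
        for j in order:
            train_proteins.add(proteins[j])
            rows += int(counts[proteins[j]])
            if rows >= target_rows:
                break
        mask = ds.proteins.isin(train_proteins).to_numpy()
        train_idx, test_idx = np.flatnonzero(mask), np.flatnonzero(~mask)
        if len(test_idx) == 0:
            raise ValueError("by_protein split left no test proteins")
    return ds.subset(train_idx), ds.subset(test_idx)


# ---------------------------------------------------------------------------
# Estimators

class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis: PLS regression on one-hot class targets.

    Prediction takes the argmax over predicted class columns; the
    predicted column for a class serves as its continuous score.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        Y = np.column_stack([(y == c).astype(float) for c in self.classes_])
        n_comp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=n_comp, scale=False)
        self.pls_.fit(X, Y)
        return self

    def decision_function(self, X):
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        if len(self.classes_) == 2:
            return scores[:, 1] - scores[:, 0]
        return scores

    def predict(self, X):
        scores = self.pls_.predict(np.asarray(X, dtype=float))
        return self.classes_[np.argmax(scores, axis=1)]

    def class_scores(self, X) -> np.ndarray:
        """Raw predicted one-hot columns, ordered as ``classes_``."""
        return self.pls_.predict(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """One learner configuration: algorithm, task, tuning grid, CV folds."""

    algorithm: str
    task: str
    grid: Mapping[str, Sequence] | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.task not in ("binary", "ternary", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm == "naive_bayes" and self.task == "regression":
            raise ValueError("naive_bayes supports classification only")


def default_grid(algorithm: str, task: str) -> dict[str, list]:
    """Default tuning grids, config-overridable."""
    if algorithm == "svm_rbf":
        return {"est__C": [0.25, 0.5, 1.0, 2.0, 4.0]}
    if algorithm == "random_forest":
        return {"est__max_features": [2, 3, 5]}
    if algorithm == "naive_bayes":
        return {}
    if algorithm == "knn":
        return {"est__n_neighbors": [3, 5, 7, 9, 11]}
    if algorithm == "neural_net":
        return {
            "est__hidden_layer_sizes": [(1,), (3,), (5,)],
            "est__alpha": [0.0, 0.01, 0.1],
        }
    if algorithm == "pls":
        return {"est__n_components": [k + 1 for k in range(8)]}
    raise ValueError(algorithm)


def _median_heuristic_gamma(X: np.ndarray, seed: int, max_rows: int = 400) -> float:
    """RBF kernel width from the median pairwise distance of (standardized) X."""
    rng = np.random.default_rng(seed)
    if len(X) > max_rows:
        X = X[rng.choice(len(X), size=max_rows, replace=False)]
    d = pdist(X)
    d = d[d > 0]
    med = float(np.median(d)) if len(d) else 1.0
    return 1.0 / (2.0 * med * med)


def _base_estimator(spec: ModelSpec, gamma: float | None = None):
    seed, classify = spec.seed, spec.task != "regression"
    if spec.algorithm == "svm_rbf":
        g = gamma if gamma is not None else "scale"
        return SVC(kernel="rbf", gamma=g, random_state=seed) if classify else SVR(
            kernel="rbf", gamma=g
        )
    if spec.algorithm == "random_forest":
        cls = RandomForestClassifier if classify else RandomForestRegressor
        return cls(n_estimators=500, random_state=seed, n_jobs=1)
    if spec.algorithm == "naive_bayes":
        return GaussianNB()
    if spec.algorithm == "knn":
        return KNeighborsClassifier() if classify else KNeighborsRegressor()
    if spec.algorithm == "neural_net":
        cls = MLPClassifier if classify else MLPRegressor
        return cls(solver="lbfgs", max_iter=1000, random_state=seed)
    if spec.algorithm == "pls":
        return PLSDAClassifier() if classify else PLSRegression(scale=False)
    raise ValueError(spec.algorithm)


def _cv_splitter(spec: ModelSpec):
    if spec.task == "regression":
        return KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    return StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)


@dataclass
class FittedModel:
    """A tuned, refit pipeline plus its provenance."""

    pipeline: Pipeline
    spec: ModelSpec
    feature_columns: tuple[str, ...]
    best_params: dict
    tuning_trace: pd.DataFrame
    dataset_hash: str = ""

    @property
    def classes_(self) -> np.ndarray | None:
        est = self.pipeline.named_steps["est"]
        return getattr(est, "classes_", None)

    def manifest(self) -> dict:
        """Provenance: feature order, scaling parameters, tuning, seed."""
        scaler = self.pipeline.named_steps["scale"]
        return {
            "algorithm": self.spec.algorithm,
            "task": self.spec.task,
            "seed": self.spec.seed,
            "cv_folds": self.spec.cv_folds,
            "feature_columns": list(self.feature_columns),
            "standardization": {
                "mean": [float(v) for v in scaler.mean_],
                "scale": [float(v) for v in scaler.scale_],
            },
            "hyperparameters": {k: repr(v) for k, v in self.best_params.items()},
            "dataset_hash": self.dataset_hash,
        }

    def save(self, path) -> None:
        """Pickle the fitted model; a JSON manifest is written alongside."""
        import json
        import pickle
        from pathlib import Path

        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        path.with_suffix(path.suffix + ".manifest.json").write_text(
            json.dumps(self.manifest(), indent=2) + "\n"
        )

    @staticmethod
    def load(path) -> "FittedModel":
        import pickle

        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, FittedModel):
            raise TypeError(f"{path} does not contain a FittedModel")
        return model


def _check_columns(X: pd.DataFrame) -> None:
    if list(X.columns) != list(FEATURE_COLUMNS):
        missing = set(FEATURE_COLUMNS) - set(X.columns)
        extra = set(X.columns) - set(FEATURE_COLUMNS)
        raise ValueError(
            f"feature column mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )


def _targets(ds: LabeledDataset, spec: ModelSpec):
    return ds.y.to_numpy() if spec.task == "regression" else ds.labels.to_numpy()


def _make_search(train_ds: LabeledDataset, spec: ModelSpec) -> GridSearchCV:
    X = train_ds.X.to_numpy(dtype=float)
    zero_var = [c for c, v in zip(FEATURE_COLUMNS, X.var(axis=0)) if v == 0.0]
    if zero_var:
        warnings.warn(
            f"zero-variance feature column(s) {zero_var}: left unscaled", stacklevel=3
        )
    gamma = None
    if spec.algorithm == "svm_rbf":
        Xs = StandardScaler().fit_transform(X)
        gamma = _median_heuristic_gamma(Xs, spec.seed)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("est", _base_estimator(spec, gamma))]
    )
    grid = dict(spec.grid) if spec.grid is not None else default_grid(
        spec.algorithm, spec.task
    )
    scoring = "accuracy" if spec.task != "regression" else "neg_root_mean_squared_error"
    return GridSearchCV(
        pipe,
        param_grid=grid,
        scoring=scoring,
        cv=_cv_splitter(spec),
        n_jobs=1,
        refit=True,
    )


def train(train_ds: LabeledDataset, spec: ModelSpec) -> FittedModel:
    """Grid-search tune on the training set and refit the best pipeline."""
    _check_columns(train_ds.X)
    if len(train_ds) < spec.cv_folds:
        raise ValueError(
            f"{len(train_ds)} rows is fewer than cv_folds={spec.cv_folds}"
        )
    search = _make_search(train_ds, spec)
    X = train_ds.X.to_numpy(dtype=float)
    y = _targets(train_ds, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        search.fit(X, y)
    trace = pd.DataFrame(search.cv_results_)[
        ["params", "mean_test_score", "rank_test_score"]
    ]
    return FittedModel(
        pipeline=search.best_estimator_,
        spec=spec,
        feature_columns=FEATURE_COLUMNS,
        best_params=dict(search.best_params_),
        tuning_trace=trace,
        dataset_hash=_dataset_hash(train_ds),
    )


def _dataset_hash(ds: LabeledDataset) -> str:
    import hashlib

    digest = hashlib.sha256()
    digest.update(ds.X.to_numpy(dtype=float).tobytes())
    digest.update(ds.y.to_numpy(dtype=float).tobytes())
    return digest.hexdigest()[:16]


def cross_validate(
    train_ds: LabeledDataset, spec: ModelSpec, fitted: FittedModel | None = None
) -> float:
    """Seeded k-fold CV metric of the tuned model on the training set.

    Classification: pooled out-of-fold accuracy.  Regression: squared
    Pearson correlation between pooled out-of-fold predictions and the
    observed values.
    """
    if fitted is None:
        fitted = train(train_ds, spec)
    X = train_ds.X.to_numpy(dtype=float)
    y = _targets(train_ds, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        oof = cross_val_predict(
            clone(fitted.pipeline), X, y, cv=_cv_splitter(spec), n_jobs=1
        )
    if spec.task == "regression":
        return r_squared(oof, y)
    return float(np.mean(oof == y))


@dataclass
class Predictions:
    """Hard predictions plus continuous scores (classification only)."""

    labels: np.ndarray | None
    scores: np.ndarray | None
    values: np.ndarray | None


def predict(model: FittedModel, test_ds: LabeledDataset) -> Predictions:
    """Predict a test dataset; scores are for the positive ('stable') class."""
    _check_columns(test_ds.X)
    X = test_ds.X.to_numpy(dtype=float)
    if model.spec.task == "regression":
        values = np.asarray(model.pipeline.predict(X), dtype=float).ravel()
        return Predictions(labels=None, scores=None, values=values)
    labels = model.pipeline.predict(X)
    scores = positive_class_scores(model, X)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite prediction scores")
    return Predictions(labels=np.asarray(labels), scores=scores, values=None)


def positive_class_scores(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Continuous score for the positive class, for ROC curves."""
    pipe = model.pipeline
    est = pipe.named_steps["est"]
    classes = list(model.classes_)
    pos = classes.index(POSITIVE_CLASS) if POSITIVE_CLASS in classes else len(classes) - 1
    if hasattr(est, "predict_proba"):
        return np.asarray(pipe.predict_proba(X))[:, pos]
    if isinstance(est, PLSDAClassifier):
        Xt = pipe.named_steps["scale"].transform(X)
        return est.class_scores(Xt)[:, pos]
    df = np.asarray(pipe.decision_function(X))
    if df.ndim == 1:  # binary decision function scores classes_[1]
        return df if pos == 1 else -df
    return df[:, pos]


def r_squared(pred, obs) -> float:
    """Squared Pearson correlation; 0 (with a warning) for degenerate input."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if len(pred) != len(obs):
        raise ValueError("pred and obs lengths differ")
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("zero-variance predictions or observations; R^2 reported as 0")
        return 0.0
    r = pearsonr(pred, obs).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# The high-level Model / Results pair

class StabilityModel:
    """A thermostability prediction model for single point mutations.

    Parameters
    ----------
    dataset : LabeledDataset
        Forward-mutation dataset (from :func:`mutstab.datasets.build_dataset`
        or the synthetic generator).
    algorithm : str
        One of ``svm_rbf``, ``random_forest``, ``naive_bayes``, ``knn``,
        ``neural_net``, ``pls``.
    split_scheme : SplitScheme, optional
        Defaults to a seeded random 80/20 row split; pass
        ``SplitScheme("by_protein", ...)`` for a non-redundant split.
    augment : str
        ``none`` (default), ``reverse_only`` or ``combined`` reverse-
        mutation augmentation, applied before splitting.

    Examples
    --------
    >>> res = StabilityModel(ds, "svm_rbf", seed=0).fit()   # doctest: +SKIP
    >>> print(res.summary())                                 # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        algorithm: str,
        *,
        grid: Mapping[str, Sequence] | None = None,
        cv_folds: int = 10,
        seed: int = 0,
        split_scheme: SplitScheme | None = None,
        augment: str = "none",
    ):
        self.dataset = dataset
        self.spec = ModelSpec(
            algorithm=algorithm,
            task=dataset.task,
            grid=grid,
            cv_folds=cv_folds,
            seed=seed,
        )
        self.split_scheme = split_scheme or SplitScheme(seed=seed)
        self.augment = augment

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, task: str, target_name: str, algorithm: str, **kwargs
    ) -> "StabilityModel":
        """Construct from a flat frame as written by ``LabeledDataset.to_frame``."""
        return cls(LabeledDataset.from_frame(df, task, target_name), algorithm, **kwargs)

    def fit(self) -> "StabilityResults":
        ds = augment_dataset(self.dataset, self.augment)
        train_ds, test_ds = split(ds, self.split_scheme)
        fitted = train(train_ds, self.spec)
        cv_metric = cross_validate(train_ds, self.spec, fitted)
        return StabilityResults(
            model=self,
            fitted=fitted,
            train_ds=train_ds,
            test_ds=test_ds,
            cv_metric=cv_metric,
        )


class StabilityResults:
    """Fit results: CV metric, held-out test metrics, diagnostics."""

    def __init__(self, model, fitted, train_ds, test_ds, cv_metric):
        from . import metrics as _metrics  # local import avoids a cycle

        self.model = model
        self.fitted = fitted
        self.train_ds = train_ds
        self.test_ds = test_ds
        self.cv_metric = float(cv_metric)
        self._metrics = _metrics
        self.report = _metrics.evaluate_model(fitted, test_ds, cv_metric=cv_metric)

    # convenience accessors ------------------------------------------------
    @property
    def task(self) -> str:
        return self.fitted.spec.task

    @property
    def algorithm(self) -> str:
        return self.fitted.spec.algorithm

    @property
    def test_accuracy(self) -> float | None:
        return self.report.test_accuracy

    @property
    def test_auc(self) -> float | None:
        return self.report.test_auc

    @property
    def test_r2(self) -> float | None:
        return self.report.test_r2

    @property
    def confusion(self) -> pd.DataFrame | None:
        return self.report.confusion

    def evaluate(self, other_ds: LabeledDataset):
        """Evaluate the fitted model on another dataset.

        Used e.g. to score a forward-trained model on the reversed test
        set (the reverse-mutation overfitting check).
        """
        return self._metrics.evaluate_model(
            self.fitted, other_ds, cv_metric=self.cv_metric
        )

    def rfe_ranks(self, n_resamples: int = 5) -> dict[str, int]:
        """Recursive-feature-elimination ranks on the training set."""
        return self._metrics.rfe_rank(
            self.train_ds, self.fitted.spec, n_resamples=n_resamples
        )

    def summary(self) -> str:
        spec = self.fitted.spec
        metric_name = "CV R^2" if self.task == "regression" else "CV accuracy"
        lines = [
            "Thermostability prediction model",
            "=" * 48,
            f"target:        {self.train_ds.target_name}",
            f"task:          {self.task}",
            f"algorithm:     {self.algorithm}",
            f"train rows:    {len(self.train_ds)} "
            f"({self.train_ds.n_proteins} proteins)",
            f"test rows:     {len(self.test_ds)} "
            f"({self.test_ds.n_proteins} proteins)",
            f"tuned params:  {self.fitted.best_params}",
            f"{metric_name + ':':14s}{self.cv_metric:.3f}",
        ]
        if self.test_accuracy is not None:
            lines.append(f"test accuracy: {self.test_accuracy:.3f}")
        if self.test_auc is not None:
            lines.append(f"test AUC:      {self.test_auc:.3f}")
        if self.test_r2 is not None:
            lines.append(f"test R^2:      {self.test_r2:.3f}")
        if self.confusion is not None:
            lines += ["confusion matrix (rows = observed):", str(self.confusion)]
        return "\n".join(lines)
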