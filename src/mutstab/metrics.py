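"""Evaluation metrics, recursive feature elimination, and reports.

Conventions: the positive class for ROC curves is "stable"; the
coefficient of determination R^2 is the squared Pearson correlation
between predictions and observations (so Pearson's r is its square
root); ternary accuracy is plain multiclass accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datasets import LabeledDataset
from .features import FEATURE_COLUMNS
from .model import (
    POSITIVE_CLASS,
    FittedModel,
    ModelSpec,
    SplitScheme,
    _base_estimator,
    _cv_splitter,
    _targets,
    predict,
    r_squared,
    split,
)

__all__ = [
    "accuracy",
    "roc_auc",
    "roc_points",
    "r_squared",
    "confusion",
    "EvalReport",
    "evaluate_model",
    "rfe_rank",
    "baseline_single_feature",
]


def accuracy(pred_labels: Sequence, true_labels: Sequence) -> float:
    """Fraction of exactly matching labels."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(pred) != len(true):
        raise ValueError("label vectors have different lengths")
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(pred == true))


def _binary_indicator(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    if len(present) < 2:
        raise ValueError(f"need both classes for ROC, got only {sorted(present)}")
    return (labels == POSITIVE_CLASS).astype(int)


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve, 'stable' as the positive class.

    Equals the probability (with tie-averaging) that a randomly chosen
    stable row outscores a randomly chosen unstable row.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return float(roc_auc_score(_binary_indicator(labels), scores))


def roc_points(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold)."""
    fpr, tpr, thr = roc_curve(_binary_indicator(labels), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def confusion(pred_labels: Sequence, true_labels: Sequence) -> pd.DataFrame:
    """Class-by-class counts; rows = observed class, columns = predicted."""
    classes = sorted(set(np.asarray(true_labels)) | set(np.asarray(pred_labels)))
    mat = _sk_confusion(true_labels, pred_labels, labels=classes)
    return pd.DataFrame(mat, index=classes, columns=classes)


@dataclass
class EvalReport:
    """Per-model evaluation: CV and held-out test metrics plus diagnostics."""

    task: str
    algorithm: str
    cv_metric: float
    test_accuracy: float | None = None
    test_auc: float | None = None
    test_r2: float | None = None
    confusion: pd.DataFrame | None = None
    rfe_ranks: dict[str, int] | None = None

    def to_dict(self) -> dict:
        out = {
            "task": self.task,
            "algorithm": self.algorithm,
            "cv_metric": self.cv_metric,
            "test_accuracy": self.test_accuracy,
            "test_auc": self.test_auc,
            "test_r2": self.test_r2,
        }
        if self.confusion is not None:
            out["confusion"] = {
                str(obs): {str(p): int(v) for p, v in row.items()}
                for obs, row in self.confusion.to_dict(orient="index").items()
            }
        if self.rfe_ranks is not None:
            out["rfe_ranks"] = self.rfe_ranks
        return out

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_model(
    fitted: FittedModel, test_ds: LabeledDataset, cv_metric: float = float("nan")
) -> EvalReport:
    """Score a fitted model on a held-out dataset."""
    spec = fitted.spec
    preds = predict(fitted, test_ds)
    if spec.task == "regression":
        return EvalReport(
            task=spec.task,
            algorithm=spec.algorithm,
            cv_metric=cv_metric,
            test_r2=r_squared(preds.values, test_ds.y.to_numpy()),
        )
    true = test_ds.labels.to_numpy()
    auc = None
    if spec.task == "binary" and len(set(true)) == 2:
        auc = roc_auc(preds.scores, true)
    return EvalReport(
        task=spec.task,
        algorithm=spec.algorithm,
        cv_metric=cv_metric,
        test_accuracy=accuracy(preds.labels, true),
        test_auc=auc,
        confusion=confusion(preds.labels, true),
    )


# ---------------------------------------------------------------------------
# Feature selection

def _importance(
    X: np.ndarray, y: np.ndarray, cols: list[int], spec: ModelSpec, n_resamples: int
) -> np.ndarray:
    """Importance of the surviving columns, higher = more important.

    Random forests expose a native impurity importance, averaged over
    seeded bootstrap refits.  Other learners use the drop-one-column loss
    in 5-fold CV score.
    """
    rng = np.random.default_rng(spec.seed + 7 * len(cols))
    Xc = X[:, cols]
    if spec.algorithm == "random_forest":
        imps = []
        for _ in range(n_resamples):
            idx = rng.choice(len(Xc), size=len(Xc), replace=True)
            est = _base_estimator(spec)
            est.set_params(n_estimators=200, random_state=int(rng.integers(2**31)))
            est.fit(Xc[idx], y[idx])
            imps.append(est.feature_importances_)
        return np.mean(imps, axis=0)

    def cv_score(Xs: np.ndarray) -> float:
        est = _base_estimator(spec)
        if "n_components" in est.get_params():
            est.set_params(n_components=min(2, Xs.shape[1]))
        pipe = Pipeline([("scale", StandardScaler()), ("est", est)])
        scoring = (
            "accuracy" if spec.task != "regression" else "neg_root_mean_squared_error"
        )
        cv = _cv_splitter(
            ModelSpec(spec.algorithm, spec.task, cv_folds=5, seed=spec.seed)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(np.mean(cross_val_score(pipe, Xs, y, cv=cv, scoring=scoring)))

    base = cv_score(Xc)
    losses = []
    for j in range(Xc.shape[1]):
        keep = [k for k in range(Xc.shape[1]) if k != j]
        losses.append(base - cv_score(Xc[:, keep]))
    return np.asarray(losses)


def rfe_rank(
    ds: LabeledDataset, spec: ModelSpec, n_resamples: int = 5
) -> dict[str, int]:
    """Recursive feature elimination ranking of the nine descriptors.

    Backward elimination from the full set down to one feature: at each
    size the least important feature is dropped and receives the current
    size as its rank, so the last survivor has rank 1.  Ties break by
    column order.
    """
    if ds.X.shape[1] < 2:
        raise ValueError("RFE needs at least two features")
    X = ds.X.to_numpy(dtype=float)
    y = _targets(ds, spec)
    cols = list(range(X.shape[1]))
    ranks: dict[str, int] = {}
    while len(cols) > 1:
        imp = _importance(X, y, cols, spec, n_resamples)
        worst = int(np.argmin(imp))  # argmin takes the first on ties
        ranks[FEATURE_COLUMNS[cols[worst]]] = len(cols)
        cols.pop(worst)
    ranks[FEATURE_COLUMNS[cols[0]]] = 1
    return ranks


def baseline_single_feature(
    ds: LabeledDataset,
    feature: str = "rosetta_ddg",
    seed: int = 0,
    train_fraction: float = 0.8,
) -> float:
    """Held-out R^2 of an ordinary least squares fit on one feature.

    The comparison baseline for the full nine-descriptor models: a simple
    linear regression of the target on a single descriptor, scored on the
    same kind of random 80/20 split.
    """
    if feature not in ds.X.columns:
        raise ValueError(f"unknown feature {feature!r}")
    train_ds, test_ds = split(ds, SplitScheme("random_row", train_fraction, seed))
    x = train_ds.X[feature].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    slope, intercept = np.polyfit(x, train_ds.y.to_numpy(dtype=float), 1)
    pred = slope * test_ds.X[feature].to_numpy(dtype=float) + intercept
    return r_squared(pred, test_ds.y.to_numpy())
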