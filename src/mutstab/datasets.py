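"""Labeled datasets: feature matrix + target + grouping for splits."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, PropertyTable, feature_frame
from .records import (
    CurationConfig,
    CurationError,
    MutationRecord,
    StabilityClass,
    label,
)

TASKS = ("binary", "ternary", "regression")

_TASK_CLASSES = {
    "binary": (StabilityClass.STABLE, StabilityClass.UNSTABLE),
    "ternary": (StabilityClass.STABLE, StabilityClass.NEUTRAL, StabilityClass.UNSTABLE),
}


@dataclass
class LabeledDataset:
    """A modeling-ready dataset.

    Attributes
    ----------
    X : DataFrame
        Feature matrix, columns exactly ``FEATURE_COLUMNS``.
    y : Series
        Continuous target (ddG in kcal/mol or dTm in degC).
    labels : Series
        Stability class of each row (string values).
    proteins : Series
        Protein identifier per row, for group-aware splitting.
    direction : Series
        Row provenance, "fwd" for measured mutations, "rev" for
        hypothetical reverse mutations.
    """

    X: pd.DataFrame
    y: pd.Series
    labels: pd.Series
    proteins: pd.Series
    direction: pd.Series
    task: str
    target_name: str

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(FEATURE_COLUMNS):
            raise ValueError(
                f"feature columns must be {list(FEATURE_COLUMNS)}, got {list(self.X.columns)}"
            )
        n = len(self.X)
        for name in ("y", "labels", "proteins", "direction"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != feature matrix length")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_proteins(self) -> int:
        return self.proteins.nunique()

    def class_counts(self) -> dict[str, int]:
        counts = self.labels.value_counts().to_dict()
        return {str(k): int(v) for k, v in counts.items()}

    def subset(self, mask) -> "LabeledDataset":
        idx = np.asarray(mask)
        return LabeledDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y.iloc[idx].reset_index(drop=True),
            labels=self.labels.iloc[idx].reset_index(drop=True),
            proteins=self.proteins.iloc[idx].reset_index(drop=True),
            direction=self.direction.iloc[idx].reset_index(drop=True),
            task=self.task,
            target_name=self.target_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat frame: protein, direction, features, target, label."""
        out = self.X.copy()
        out.insert(0, "protein_id", self.proteins.values)
        out.insert(1, "direction", self.direction.values)
        out["target"] = self.y.values
        out["label"] = self.labels.values
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, task: str, target_name: str) -> "LabeledDataset":
        return cls(
            X=df[list(FEATURE_COLUMNS)].reset_index(drop=True),
            y=df["target"].reset_index(drop=True),
            labels=df["label"].astype(str).reset_index(drop=True),
            proteins=df["protein_id"].astype(str).reset_index(drop=True),
            direction=df["direction"].astype(str).reset_index(drop=True)
            if "direction" in df
            else pd.Series(["fwd"] * len(df)),
            task=task,
            target_name=target_name,
        )

    @classmethod
    def concat(cls, parts: Sequence["LabeledDataset"]) -> "LabeledDataset":
        first = parts[0]
        return cls(
            X=pd.concat([p.X for p in parts], ignore_index=True),
            y=pd.concat([p.y for p in parts], ignore_index=True),
            labels=pd.concat([p.labels for p in parts], ignore_index=True),
            proteins=pd.concat([p.proteins for p in parts], ignore_index=True),
            direction=pd.concat([p.direction for p in parts], ignore_index=True),
            task=first.task,
            target_name=first.target_name,
        )


def build_dataset(
    records: Iterable[MutationRecord],
    config: CurationConfig = CurationConfig(),
    target: str = "ddg",
    task: str = "regression",
    table: PropertyTable | None = None,
) -> LabeledDataset:
    """Assemble a labeled dataset from curated records.

    Classification tasks drop gap-zone (excluded) rows — and, for binary,
    neutral rows; regression keeps every curated record.  Raises if a
    required class has no members.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    records = list(records)
    bounds = config.bounds_for(target)
    classes = [label(r.target(target), bounds) for r in records]

    if task in _TASK_CLASSES:
        wanted = _TASK_CLASSES[task]
        keep = [i for i, c in enumerate(classes) if c in wanted]
        present = {classes[i] for i in keep}
        for cls_ in wanted:
            if cls_ not in present:
                raise CurationError(
                    f"class {cls_.value!r} has no members in the {task} dataset"
                )
        records = [records[i] for i in keep]
        classes = [classes[i] for i in keep]

    X = feature_frame(records, table)
    return LabeledDataset(
        X=X,
        y=pd.Series([r.target(target) for r in records], name=target, dtype=float),
        labels=pd.Series([c.value for c in classes], name="label"),
        proteins=pd.Series([r.protein_id for r in records], name="protein_id"),
        direction=pd.Series(["fwd"] * len(records), name="direction"),
        task=task,
        target_name=target,
    )
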