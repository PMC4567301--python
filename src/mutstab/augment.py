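"""Hypothetical reverse-mutation data augmentation.

ddG and dTm are state functions: reversing a mutation A->B into B->A
negates the measured value and every descriptor that is itself a
difference of state properties (the six physical-property deltas and the
Rosetta score).  The two site descriptors — secondary structure and
percentage exposure — describe *where* the mutation sits and are shared
by forward and reverse mutations, so they are kept.  Class labels flip
stable<->unstable; neutral (and gap-zone) rows stay put.

Because measured sets are dominated by destabilizing mutations, the
combined forward+reverse set is exactly class-balanced for binary tasks,
which is the augmentation's practical payoff.
"""

from __future__ import annotations

import pandas as pd

from .datasets import LabeledDataset
from .features import STATE_FUNCTION_COLUMNS
from .records import StabilityClass

AUGMENT_MODES = ("none", "reverse_only", "combined")


def reverse(
    features: dict, target: float, label: StabilityClass
) -> tuple[dict, float, StabilityClass]:
    """Reverse one mutation row: negate state functions, keep site descriptors."""
    out = dict(features)
    for col in STATE_FUNCTION_COLUMNS:
        out[col] = -out[col]
    return out, -target, label.flipped()


def reverse_dataset(ds: LabeledDataset) -> LabeledDataset:
    """Vectorized :func:`reverse` over a whole dataset.

    Reverse rows keep their source protein_id so protein-level splits put a
    forward mutation and its reverse on the same side.
    """
    X = ds.X.copy()
    X[list(STATE_FUNCTION_COLUMNS)] = -X[list(STATE_FUNCTION_COLUMNS)]
    labels = ds.labels.map(lambda v: StabilityClass(v).flipped().value)
    return LabeledDataset(
        X=X,
        y=-ds.y,
        labels=labels.rename("label"),
        proteins=ds.proteins.copy(),
        direction=pd.Series(["rev"] * len(ds), name="direction"),
        task=ds.task,
        target_name=ds.target_name,
    )


def augment_dataset(ds: LabeledDataset, mode: str = "combined") -> LabeledDataset:
    """Apply reverse-mutation augmentation.

    ``reverse_only`` returns just the reversed rows; ``combined`` returns
    forward rows followed by their reverses (2n rows); ``none`` is the
    identity.
    """
    if mode not in AUGMENT_MODES:
        raise ValueError(f"mode must be one of {AUGMENT_MODES}, got {mode!r}")
    if mode == "none":
        return ds
    rev = reverse_dataset(ds)
    if mode == "reverse_only":
        return rev
    return LabeledDataset.concat([ds, rev])
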