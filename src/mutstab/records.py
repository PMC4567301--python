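"""Mutation records, curation filters and stability class labels.

A :class:`MutationRecord` is one experimental measurement of a protein
single point mutation: the protein it occurs in, the substitution itself
(wild-type residue, position, mutant residue), the measurement conditions,
and the measured thermostability change — the unfolding free energy change
ddG (kcal/mol) and/or the melting temperature change dTm (degC).  The sign
convention throughout is *positive = stabilizing*.

Curation reproduces the filters used to assemble ProTherm-derived
benchmark sets: a physiological pH window, a protein-size cap, an outlier
trim on |ddG|, and averaging of replicate measurements.  Class labels
(stable / neutral / unstable) are assigned from the measured value with a
gap zone between the classes; records falling in a gap are *excluded*
from classification tasks but retained for regression.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

SECONDARY_STRUCTURES = ("helix", "sheet", "coil", "turn")

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class MutationParseError(ValueError):
    """Raised for malformed or chemically invalid mutation tokens."""


class CurationError(ValueError):
    """Raised when curation or dataset assembly cannot proceed."""


class StabilityClass(str, Enum):
    """Ternary stability class, plus the gap-zone sentinel."""

    STABLE = "stable"
    NEUTRAL = "neutral"
    UNSTABLE = "unstable"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    def flipped(self) -> "StabilityClass":
        """Class of the reverse mutation: stable<->unstable, others fixed."""
        if self is StabilityClass.STABLE:
            return StabilityClass.UNSTABLE
        if self is StabilityClass.UNSTABLE:
            return StabilityClass.STABLE
        return self


@dataclass(frozen=True)
class CurationConfig:
    """Curation filters and class boundaries.

    Defaults follow the benchmark construction protocol: pH window
    [6, 8], monomeric proteins of at most 300 residues, |ddG| trimmed at
    10 kcal/mol (ddG sets only), class boundaries (-1, -0.5, 0.5, 1)
    kcal/mol for ddG and (-3, -1, 1, 3) degC for dTm.
    """

    ph_min: float = 6.0
    ph_max: float = 8.0
    max_length: int = 300
    ddg_abs_cap: float = 10.0
    ddg_bounds: tuple[float, float, float, float] = (-1.0, -0.5, 0.5, 1.0)
    dtm_bounds: tuple[float, float, float, float] = (-3.0, -1.0, 1.0, 3.0)
    #: apply the |ddG| trim after replicate averaging (True) or before
    cap_after_averaging: bool = True
    #: negate targets on input for sources where positive = destabilizing
    flip_sign: bool = False

    def __post_init__(self) -> None:
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be < ph_max")
        for bounds in (self.ddg_bounds, self.dtm_bounds):
            if not all(a < b for a, b in zip(bounds, bounds[1:])):
                raise ValueError(f"class bounds must be strictly increasing: {bounds}")

    def bounds_for(self, target: str) -> tuple[float, float, float, float]:
        if target == "ddg":
            return self.ddg_bounds
        if target == "dtm":
            return self.dtm_bounds
        raise ValueError(f"unknown target {target!r}; expected 'ddg' or 'dtm'")


@dataclass
class MutationRecord:
    """One measured single point mutation with conditions and structure context."""

    protein_id: str
    wt_aa: str
    position: int
    mut_aa: str
    chain: str = ""
    ph: float | None = None
    protein_length: int | None = None
    ddg: float | None = None
    dtm: float | None = None
    sec_struct: str | None = None
    asa_raw: float | None = None
    rosetta_ddg: float | None = None

    def __post_init__(self) -> None:
        self.wt_aa = self.wt_aa.upper()
        self.mut_aa = self.mut_aa.upper()
        if self.wt_aa not in AMINO_ACIDS:
            raise MutationParseError(f"unknown wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in AMINO_ACIDS:
            raise MutationParseError(f"unknown mutant residue {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise MutationParseError(
                f"silent mutation {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        if self.ddg is None and self.dtm is None:
            raise ValueError("record carries neither a ddG nor a dTm measurement")
        if self.sec_struct is not None and self.sec_struct not in SECONDARY_STRUCTURES:
            raise ValueError(
                f"sec_struct must be one of {SECONDARY_STRUCTURES}, got {self.sec_struct!r}"
            )
        if self.asa_raw is not None and self.asa_raw < 0:
            raise ValueError(f"asa_raw must be >= 0, got {self.asa_raw}")

    @property
    def mutation(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    def target(self, name: str) -> float | None:
        if name == "ddg":
            return self.ddg
        if name == "dtm":
            return self.dtm
        raise ValueError(f"unknown target {name!r}")

    def replicate_key(self) -> tuple:
        return (self.protein_id, self.chain, self.wt_aa, self.position, self.mut_aa)


def parse_mutation(token: str) -> tuple[str, int, str]:
    """Parse ``"I3V"``-style notation into (wt_aa, position, mut_aa)."""
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation token {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if wt not in AMINO_ACIDS:
        raise MutationParseError(f"unknown wild-type residue in {token!r}")
    if mut not in AMINO_ACIDS:
        raise MutationParseError(f"unknown mutant residue in {token!r}")
    if wt == mut:
        raise MutationParseError(f"silent mutation {token!r} (wt == mut)")
    if pos < 1:
        raise MutationParseError(f"position must be >= 1 in {token!r}")
    return wt, pos, mut


def label(value: float, bounds: Sequence[float]) -> StabilityClass:
    """Assign a stability class from a measured value.

    With bounds (b1, b2, b3, b4): value <= b1 is unstable, b2 <= value <= b3
    is neutral, value >= b4 is stable; values inside the open gaps (b1, b2)
    or (b3, b4) are excluded.  All class boundaries are inclusive.
    """
    b1, b2, b3, b4 = bounds
    if not (b1 < b2 < b3 < b4):
        raise ValueError(f"bounds must be strictly increasing: {bounds}")
    if not math.isfinite(value):
        raise ValueError(f"cannot label non-finite value {value!r}")
    if value <= b1:
        return StabilityClass.UNSTABLE
    if value >= b4:
        return StabilityClass.STABLE
    if b2 <= value <= b3:
        return StabilityClass.NEUTRAL
    return StabilityClass.EXCLUDED


def curate(
    records: Iterable[MutationRecord],
    config: CurationConfig = CurationConfig(),
    target: str = "ddg",
) -> list[MutationRecord]:
    """Apply the curation filters for one target and collapse replicates.

    Steps, in order: drop records missing the target; (optionally) flip the
    sign convention; drop records outside the pH window or longer than the
    size cap; average replicate measurements of the same mutation; trim
    |ddG| above the cap (ddG target only; before or after averaging per
    config).  Output is sorted by (protein_id, chain, position, mut_aa) so
    downstream seeded splits are reproducible.
    """
    config.bounds_for(target)  # validates target name
    kept: list[MutationRecord] = []
    for rec in records:
        value = rec.target(target)
        if value is None or not math.isfinite(value):
            continue
        if config.flip_sign:
            rec = replace(rec, **{target: -value})
            value = -value
        if rec.ph is not None and not (config.ph_min <= rec.ph <= config.ph_max):
            continue
        if rec.protein_length is not None and rec.protein_length > config.max_length:
            continue
        if (
            target == "ddg"
            and not config.cap_after_averaging
            and abs(value) > config.ddg_abs_cap
        ):
            continue
        kept.append(rec)

    # replicate averaging: same (protein, chain, wt, pos, mut) -> mean target
    groups: dict[tuple, list[MutationRecord]] = {}
    for rec in kept:
        groups.setdefault(rec.replicate_key(), []).append(rec)
    merged: list[MutationRecord] = []
    for group in groups.values():
        first = group[0]
        if len(group) > 1:
            mean = sum(r.target(target) for r in group) / len(group)
            first = replace(first, **{target: mean})
        merged.append(first)

    if target == "ddg" and config.cap_after_averaging:
        merged = [r for r in merged if abs(r.ddg) <= config.ddg_abs_cap]

    merged.sort(key=lambda r: (r.protein_id, r.chain, r.position, r.mut_aa))
    if not merged:
        raise CurationError(f"no records survive curation for target {target!r}")
    return merged


# ---------------------------------------------------------------------------
# Tabular I/O

#: canonical column names of the mutation-table CSV/TSV schema
TABLE_COLUMNS = (
    "protein_id",
    "chain",
    "mutation",
    "ph",
    "protein_length",
    "ddg",
    "dtm",
    "sec_struct",
    "asa_raw",
    "rosetta_ddg",
)

_FLOAT_FIELDS = {"ph", "ddg", "dtm", "asa_raw", "rosetta_ddg"}
_INT_FIELDS = {"protein_length"}


def read_mutation_table(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[MutationRecord]:
    """Read a CSV/TSV mutation table into records.

    ``column_map`` maps canonical names (``TABLE_COLUMNS``) to the file's
    column names when they differ.  The delimiter is inferred from the file
    extension unless given.  Empty fields are missing values.  The mutation
    may be a single ``mutation`` token ("I3V") or split ``wt_aa`` /
    ``position`` / ``mut_aa`` columns.
    """
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    column_map = dict(column_map or {})

    def col(row: dict, name: str) -> str | None:
        raw = row.get(column_map.get(name, name))
        if raw is None or str(raw).strip() == "":
            return None
        return str(raw).strip()

    records: list[MutationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter=sep
        )
        for row in reader:
            token = col(row, "mutation")
            if token is not None:
                wt, pos, mut = parse_mutation(token)
            else:
                wt = col(row, "wt_aa")
                mut = col(row, "mut_aa")
                pos_s = col(row, "position")
                if wt is None or mut is None or pos_s is None:
                    raise MutationParseError(
                        "row lacks both a 'mutation' token and wt_aa/position/mut_aa"
                    )
                wt, pos, mut = wt.upper(), int(pos_s), mut.upper()
            kwargs: dict = {}
            for name in _FLOAT_FIELDS:
                v = col(row, name)
                kwargs[name] = float(v) if v is not None else None
            for name in _INT_FIELDS:
                v = col(row, name)
                kwargs[name] = int(float(v)) if v is not None else None
            records.append(
                MutationRecord(
                    protein_id=col(row, "protein_id") or "",
                    chain=col(row, "chain") or "",
                    wt_aa=wt,
                    position=pos,
                    mut_aa=mut,
                    sec_struct=col(row, "sec_struct"),
                    **kwargs,
                )
            )
    return records


def write_mutation_table(records: Iterable[MutationRecord], path, sep: str | None = None) -> None:
    """Write records in the canonical mutation-table schema."""
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.protein_id,
                    r.chain,
                    r.mutation,
                    _fmt(r.ph),
                    _fmt(r.protein_length),
                    _fmt(r.ddg),
                    _fmt(r.dtm),
                    r.sec_struct or "",
                    _fmt(r.asa_raw),
                    _fmt(r.rosetta_ddg),
                ]
            )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
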