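"""The nine-descriptor featurization layer.

Each mutation is described by three layers:

1. *physical*: differences (mutant minus wild type) of six per-residue
   physical properties — molecular weight, formal charge, aromaticity,
   hydrophobicity, van der Waals volume, and extended-state solvent
   accessible surface area;
2. *structural*: the secondary structure at the mutation site encoded as
   an ordinal (helix=1, sheet=2, coil=3, turn=4) and the percentage
   solvent exposure of the wild-type residue, i.e. its raw ASA divided by
   the ASA of residue X in an extended Ala-X-Ala tripeptide;
3. *energetic*: a Rosetta folding free energy change computed externally
   and consumed here as an input column.

Property scales ship as plain-text CSV tables under ``mutstab/data`` and
can be overridden record-free via :meth:`PropertyTable.with_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from importlib import resources
from typing import Mapping

import pandas as pd

from .records import AMINO_ACIDS, MutationRecord

#: fixed descriptor order of every feature matrix
FEATURE_COLUMNS = (
    "delta_MW",
    "delta_Chg",
    "delta_ARM",
    "delta_Hydro",
    "delta_VdwV",
    "delta_SASA",
    "SecSt",
    "ASA_pct",
    "rosetta_ddg",
)

#: the six differenced physical properties, keyed by descriptor name
PROPERTY_FILES = {
    "delta_MW": "molecular_weight.csv",
    "delta_Chg": "formal_charge.csv",
    "delta_ARM": "aromaticity.csv",
    "delta_Hydro": "hydrophobicity.csv",
    "delta_VdwV": "vdw_volume.csv",
    "delta_SASA": "sasa_tripeptide.csv",
}

#: descriptors that flip sign under mutation reversal (state functions)
STATE_FUNCTION_COLUMNS = (
    "delta_MW",
    "delta_Chg",
    "delta_ARM",
    "delta_Hydro",
    "delta_VdwV",
    "delta_SASA",
    "rosetta_ddg",
)

SECONDARY_CODES = {"helix": 1, "sheet": 2, "coil": 3, "turn": 4}


def _load_scale(filename: str) -> dict[str, float]:
    with resources.files("mutstab.data").joinpath(filename).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["residue"], df["value"].astype(float)))


@dataclass(frozen=True)
class PropertyTable:
    """Per-residue numeric scales for the six physical properties.

    ``sasa`` doubles as the extended-state Ala-X-Ala denominator used to
    normalize raw ASA into percentage exposure.
    """

    molecular_weight: Mapping[str, float]
    formal_charge: Mapping[str, float]
    aromaticity: Mapping[str, float]
    hydrophobicity: Mapping[str, float]
    vdw_volume: Mapping[str, float]
    sasa: Mapping[str, float]

    _BY_DESCRIPTOR = {
        "delta_MW": "molecular_weight",
        "delta_Chg": "formal_charge",
        "delta_ARM": "aromaticity",
        "delta_Hydro": "hydrophobicity",
        "delta_VdwV": "vdw_volume",
        "delta_SASA": "sasa",
    }

    def __post_init__(self) -> None:
        for name in self._BY_DESCRIPTOR.values():
            scale = getattr(self, name)
            missing = AMINO_ACIDS - set(scale)
            if missing:
                raise ValueError(f"{name} scale lacks residues {sorted(missing)}")

    @classmethod
    def default(cls) -> "PropertyTable":
        return cls(
            molecular_weight=_load_scale("molecular_weight.csv"),
            formal_charge=_load_scale("formal_charge.csv"),
            aromaticity=_load_scale("aromaticity.csv"),
            hydrophobicity=_load_scale("hydrophobicity.csv"),
            vdw_volume=_load_scale("vdw_volume.csv"),
            sasa=_load_scale("sasa_tripeptide.csv"),
        )

    def with_scale(self, name: str, scale: Mapping[str, float]) -> "PropertyTable":
        """Return a copy with one property scale replaced."""
        if name not in self._BY_DESCRIPTOR.values():
            raise ValueError(f"unknown property {name!r}")
        return _dc_replace(self, **{name: dict(scale)})

    def scale_for(self, descriptor: str) -> Mapping[str, float]:
        try:
            return getattr(self, self._BY_DESCRIPTOR[descriptor])
        except KeyError:
            raise ValueError(f"unknown descriptor {descriptor!r}") from None


_DEFAULT_TABLE: PropertyTable | None = None


def default_table() -> PropertyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = PropertyTable.default()
    return _DEFAULT_TABLE


def delta_properties(
    wt_aa: str, mut_aa: str, table: PropertyTable | None = None
) -> dict[str, float]:
    """Mutant-minus-wild-type difference of the six physical properties."""
    table = table or default_table()
    deltas: dict[str, float] = {}
    for descriptor in PROPERTY_FILES:
        scale = table.scale_for(descriptor)
        for aa in (wt_aa, mut_aa):
            if aa not in scale:
                raise KeyError(f"residue {aa!r} absent from {descriptor} scale")
        deltas[descriptor] = scale[mut_aa] - scale[wt_aa]
    return deltas


def encode_secondary(ss: str) -> int:
    """Ordinal encoding of the secondary structure at the mutation site."""
    try:
        return SECONDARY_CODES[ss]
    except KeyError:
        raise ValueError(
            f"unknown secondary structure {ss!r}; expected one of "
            f"{sorted(SECONDARY_CODES)}"
        ) from None


def asa_percent(asa_raw: float, wt_aa: str, table: PropertyTable | None = None) -> float:
    """Percentage solvent exposure relative to the extended-state reference.

    Not clipped at 100: an observed ASA can exceed the Ala-X-Ala value.
    """
    if asa_raw < 0:
        raise ValueError(f"asa_raw must be >= 0, got {asa_raw}")
    table = table or default_table()
    return 100.0 * asa_raw / table.sasa[wt_aa]


def featurize(record: MutationRecord, table: PropertyTable | None = None) -> dict[str, float]:
    """Assemble the nine descriptors for one mutation, in fixed order.

    Raises if any structural/energetic input is missing — there is no
    silent imputation.
    """
    table = table or default_table()
    for field_name in ("sec_struct", "asa_raw", "rosetta_ddg"):
        if getattr(record, field_name) is None:
            raise ValueError(
                f"cannot featurize {record.protein_id} {record.mutation}: "
                f"missing {field_name}"
            )
    vec = delta_properties(record.wt_aa, record.mut_aa, table)
    vec["SecSt"] = encode_secondary(record.sec_struct)
    vec["ASA_pct"] = asa_percent(record.asa_raw, record.wt_aa, table)
    vec["rosetta_ddg"] = record.rosetta_ddg
    return {name: vec[name] for name in FEATURE_COLUMNS}


def feature_frame(records, table: PropertyTable | None = None) -> pd.DataFrame:
    """Feature matrix (n_records x 9) with columns in ``FEATURE_COLUMNS`` order."""
    table = table or default_table()
    rows = [featurize(r, table) for r in records]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
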