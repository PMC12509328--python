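"""Chemical registry for bisphenols and their glucuronides.

Holds per-chemical physicochemical identity (molar masses, logP, pKa) and the
set of Caco-2 apparent-permeability estimates from in vitro measurement and
QSAR prediction. Property values from multiple prediction sources are pooled
by arithmetic averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "BISPHENOLS",
    "GLUCURONIC_ADDUCT_MW",
    "ChemicalSpec",
    "average_property",
    "load_chemical_table",
    "default_registry",
]

BISPHENOLS = ("BPA", "BPAF", "BPB", "BPE", "BPF", "BPM", "BPS")

#: Net mass gained on glucuronic acid conjugation (g/mol).
GLUCURONIC_ADDUCT_MW = 176.12


@dataclass
class PappValue:
    """One apparent-permeability estimate, 1e-6 cm/s, tagged with its source."""

    value: float
    source: str  # in_vitro | QSAR-K | QSAR-L

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"Papp must be positive, got {self.value}")


@dataclass
class ChemicalSpec:
    """Physicochemical identity of a bisphenol and its glucuronide."""

    name: str
    mw_parent: float
    mw_glucuronide: float | None = None
    logp: float | None = None
    pka: float | None = None
    papp_values: list[PappValue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mw_parent > 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.mw_glucuronide is None:
            self.mw_glucuronide = self.mw_parent + GLUCURONIC_ADDUCT_MW
        if not self.mw_glucuronide > self.mw_parent:
            raise ValueError(
                f"{self.name}: glucuronide MW ({self.mw_glucuronide}) must "
                f"exceed parent MW ({self.mw_parent})"
            )

    def papp_list(self) -> list[float]:
        return [p.value for p in self.papp_values]


def average_property(values) -> float:
    """Arithmetic mean of property estimates from multiple sources.

    Raises ValueError on an empty or non-finite input.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot average an empty list of property values")
    if any(pd.isna(v) or v in (float("inf"), float("-inf")) for v in vals):
        raise ValueError("property values must be finite")
    return sum(vals) / len(vals)


def _read_csv(path_or_buf) -> pd.DataFrame:
    return pd.read_csv(path_or_buf, comment="#", skip_blank_lines=True)


def load_chemical_table(source, papp_source=None) -> dict[str, ChemicalSpec]:
    """Build a chemical registry from a delimited property table.

    ``source`` is a path or buffer with columns name, mw_parent, logp, pka and
    optionally mw_glucuronide (defaults to parent + glucuronic adduct mass).
    ``papp_source``, if given, is a long-format table (chemical, source,
    papp_1e6_cm_s) of apparent-permeability estimates attached per chemical.
    """
    df = _read_csv(source)
    required = {"name", "mw_parent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemical table missing columns: {sorted(missing)}")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate chemical names: {dups}")

    registry: dict[str, ChemicalSpec] = {}
    for _, row in df.iterrows():
        mw_g = row.get("mw_glucuronide")
        registry[row["name"]] = ChemicalSpec(
            name=row["name"],
            mw_parent=float(row["mw_parent"]),
            mw_glucuronide=None if pd.isna(mw_g) else float(mw_g),
            logp=float(row["logp"]) if "logp" in df.columns else None,
            pka=float(row["pka"]) if "pka" in df.columns else None,
        )

    if papp_source is not None:
        papp = _read_csv(papp_source)
        for _, row in papp.iterrows():
            name = row["chemical"]
            if name not in registry:
                raise ValueError(f"Papp entry for unknown chemical {name!r}")
            registry[name].papp_values.append(
                PappValue(float(row["papp_1e6_cm_s"]), str(row["source"]))
            )
    return registry


def default_registry() -> dict[str, ChemicalSpec]:
    """Registry of the seven bisphenols with packaged property tables.

    Papp values come from the packaged synthetic placeholder table; replace
    via :func:`load_chemical_table` to use measured/predicted inputs.
    """
    data = resources.files("bispbk.data")
    with resources.as_file(data / "chemicals.csv") as chem_path, resources.as_file(
        data / "papp_synthetic.csv"
    ) as papp_path:
        return load_chemical_table(chem_path, papp_path)
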