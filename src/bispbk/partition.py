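"""Tissue:blood partition coefficients for the model compartments.

Per-organ Kp values and plasma unbound fractions are inputs (computed
externally by tissue-composition methods); this module implements only the
combination rules: volume-weighted lumping of constituent organs into
combined compartments and the breast rule (breast Kp = fat fraction of
breast tissue, 24.5%, times the adipose Kp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "BREAST_FAT_FRACTION",
    "PartitionSet",
    "combine_kp",
    "breast_kp",
    "load_kp_table",
]

#: Fat volume fraction of breast tissue.
BREAST_FAT_FRACTION = 0.245

#: Compartments every simulation-ready PartitionSet must cover.
REQUIRED_ORGANS = ("liver", "kidney", "gut", "slow", "rapid")


@dataclass
class PartitionSet:
    """Kp maps for parent and glucuronide plus the plasma unbound fractions."""

    kp_parent: dict = field(default_factory=dict)
    kp_glucuronide: dict = field(default_factory=dict)
    fu_parent: float = 1.0
    fu_glucuronide: float = 1.0

    def __post_init__(self) -> None:
        for label, kps in [("parent", self.kp_parent), ("glucuronide", self.kp_glucuronide)]:
            for organ, kp in kps.items():
                if not kp > 0:
                    raise ValueError(f"{label} Kp for {organ!r} must be positive")
        for label, fu in [("parent", self.fu_parent), ("glucuronide", self.fu_glucuronide)]:
            if not 0 < fu <= 1:
                raise ValueError(f"fu ({label}) must be in (0, 1], got {fu}")

    def validate_coverage(self, compartments) -> None:
        """Require a Kp entry for every perfusion compartment requested."""
        for analyte, kps in [("parent", self.kp_parent), ("glucuronide", self.kp_glucuronide)]:
            missing = [c for c in compartments if c not in kps]
            if missing:
                raise ValueError(f"missing {analyte} Kp for compartments: {missing}")

    def kp(self, analyte: str, organ: str) -> float:
        kps = self.kp_parent if analyte == "parent" else self.kp_glucuronide
        return kps[organ]


def combine_kp(organ_kps: dict, weights: dict) -> float:
    """Volume-weighted lumped Kp for a combined compartment."""
    if set(organ_kps) != set(weights):
        raise ValueError("organ sets of kps and weights differ")
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {wsum}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    return sum(weights[o] * organ_kps[o] for o in organ_kps)


def breast_kp(kp_adipose: float) -> float:
    """Breast Kp from the adipose Kp and the breast fat volume fraction."""
    if not kp_adipose > 0:
        raise ValueError("adipose Kp must be positive")
    return BREAST_FAT_FRACTION * kp_adipose


def load_kp_table(kp_source, fu_source=None) -> dict[str, PartitionSet]:
    """Build per-chemical PartitionSets from delimited Kp (+fu) tables.

    ``kp_source`` columns: chemical, organ, kp_parent, kp_glucuronide.
    Breast entries are derived from adipose when absent. ``fu_source``
    columns: chemical, fu_parent, fu_glucuronide.
    """
    kp = pd.read_csv(kp_source, comment="#", skip_blank_lines=True)
    fu = (
        pd.read_csv(fu_source, comment="#", skip_blank_lines=True).set_index("chemical")
        if fu_source is not None
        else None
    )
    out: dict[str, PartitionSet] = {}
    for chem, grp in kp.groupby("chemical"):
        kpp = dict(zip(grp["organ"], grp["kp_parent"].astype(float)))
        kpg = dict(zip(grp["organ"], grp["kp_glucuronide"].astype(float)))
        for kps in (kpp, kpg):
            if "breast" not in kps:
                if "adipose" not in kps:
                    raise ValueError(
                        f"{chem}: no breast Kp and no adipose Kp to derive it from"
                    )
                kps["breast"] = breast_kp(kps["adipose"])
        missing = [o for o in REQUIRED_ORGANS if o not in kpp]
        if missing:
            raise ValueError(f"{chem}: Kp table missing compartments {missing}")
        kwargs = {}
        if fu is not None and chem in fu.index:
            kwargs = {
                "fu_parent": float(fu.loc[chem, "fu_parent"]),
                "fu_glucuronide": float(fu.loc[chem, "fu_glucuronide"]),
            }
        out[chem] = PartitionSet(kp_parent=kpp, kp_glucuronide=kpg, **kwargs)
    return out


def default_partition_sets() -> dict[str, PartitionSet]:
    """Packaged synthetic placeholder Kp/fu tables for the seven bisphenols."""
    data = resources.files("bispbk.data")
    with resources.as_file(data / "kp_synthetic.csv") as kp_path, resources.as_file(
        data / "fu_synthetic.csv"
    ) as fu_path:
        return load_kp_table(kp_path, fu_path)
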