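"""Organism models: species/sex/age physiologies for the PBK simulator.

Each physiology carries body weight, cardiac output, organ volume fractions
(of body weight, assuming unit tissue density), blood-flow fractions (of
cardiac output), gastric-emptying half-time, glomerular filtration rate, bile
flow and the UGT ontogeny class. The thyroid and gonadal (testes or breasts)
compartments exist only in the human models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

__all__ = ["Physiology", "load_physiology_table", "default_physiologies"]

#: Perfused compartments in flow-fraction order. "gonad" is testes in male
#: models and breasts in the woman model.
PERFUSED = ("liver", "gut", "kidney", "slow", "rapid", "thyroid", "gonad")
HUMAN_ONLY = ("thyroid", "gonad")


@dataclass
class Physiology:
    label: str  # rat | man | woman | child | toddler
    species: str  # human | rat
    sex: str  # male | female
    bw: float  # kg
    height: float  # cm
    cardiac_output: float  # L/h
    gest: float  # gastric emptying half-time, h
    gfr: float  # glomerular filtration rate, L/h
    bile_flow: float  # L/day
    intestinal_radius: float  # cm
    ugt_class: str  # adult | early_childhood
    vol_frac: dict = field(default_factory=dict)  # organ -> fraction of bw
    flow_frac: dict = field(default_factory=dict)  # organ -> fraction of CO
    vf_blood: float = 0.075

    def __post_init__(self) -> None:
        for name, val in [
            ("bw", self.bw),
            ("cardiac_output", self.cardiac_output),
            ("gest", self.gest),
            ("gfr", self.gfr),
            ("bile_flow", self.bile_flow),
            ("intestinal_radius", self.intestinal_radius),
        ]:
            if not val > 0:
                raise ValueError(f"{self.label}: {name} must be positive, got {val}")
        if self.species != "human":
            for organ in HUMAN_ONLY:
                if self.vol_frac.get(organ, 0) or self.flow_frac.get(organ, 0):
                    raise ValueError(
                        f"{self.label}: {organ} compartment is human-only"
                    )
        vsum = sum(self.vol_frac.values()) + self.vf_blood
        if vsum > 1 + 1e-9:
            raise ValueError(f"{self.label}: organ volume fractions sum to {vsum} > 1")
        fsum = sum(self.flow_frac.values())
        if abs(fsum - 1.0) > 1e-6:
            raise ValueError(
                f"{self.label}: blood-flow fractions sum to {fsum}, expected 1"
            )

    @property
    def compartments(self) -> tuple[str, ...]:
        """Perfused compartments present in this physiology."""
        return tuple(c for c in PERFUSED if self.vol_frac.get(c, 0) > 0)

    def volume(self, organ: str) -> float:
        """Compartment volume in L (unit density)."""
        if organ == "blood":
            return self.vf_blood * self.bw
        return self.vol_frac[organ] * self.bw

    def flow(self, organ: str) -> float:
        """Blood flow to a compartment, L/h."""
        return self.flow_frac[organ] * self.cardiac_output

    @property
    def liver_mass_g(self) -> float:
        """Liver mass in g, derived from the liver volume at unit density."""
        return self.volume("liver") * 1000.0

    def replace(self, **kw) -> "Physiology":
        return replace(self, **kw)


def load_physiology_table(source) -> dict[str, Physiology]:
    """Read a physiology table (one row per organism model)."""
    df = pd.read_csv(source, comment="#", skip_blank_lines=True)
    out: dict[str, Physiology] = {}
    for _, row in df.iterrows():
        vol = {}
        flow = {}
        for organ in PERFUSED:
            vf = float(row[f"vf_{organ}"])
            ff = float(row[f"ff_{organ}"])
            if vf > 0:
                vol[organ] = vf
            if ff > 0:
                flow[organ] = ff
        out[row["label"]] = Physiology(
            label=row["label"],
            species=row["species"],
            sex=row["sex"],
            bw=float(row["bw_kg"]),
            height=float(row["height_cm"]),
            cardiac_output=float(row["cardiac_output_L_h"]),
            gest=float(row["gest_h"]),
            gfr=float(row["gfr_L_h"]),
            bile_flow=float(row["bile_flow_L_day"]),
            intestinal_radius=float(row["intestinal_radius_cm"]),
            ugt_class=row["ugt_class"],
            vol_frac=vol,
            flow_frac=flow,
            vf_blood=float(row["vf_blood"]),
        )
    return out


def default_physiologies() -> dict[str, Physiology]:
    with resources.as_file(
        resources.files("bispbk.data") / "physiology.csv"
    ) as path:
        return load_physiology_table(path)
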