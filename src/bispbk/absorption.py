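"""Intestinal absorption parametrization.

Caco-2 apparent permeabilities (Papp) from all available sources are pooled
by arithmetic mean, converted to an in vivo effective jejunal permeability
(Peff) with the "all drugs" log-log regression of Sun and co-workers, and
turned into a first-order luminal uptake rate constant via the cylindrical
lumen relation ka = 2*Peff/R.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from .chem import ChemicalSpec, average_property

__all__ = [
    "SunRegression",
    "AbsorptionParams",
    "aggregate_papp",
    "papp_to_peff",
    "peff_to_ka",
    "parametrize_absorption",
]


@dataclass(frozen=True)
class SunRegression:
    """Constants of the Papp->Peff log-log scaling regression.

    ``log10(peff / peff_unit) = slope * log10(papp / papp_unit) + intercept``
    with the units the regression was published in (Papp in 1e-6 cm/s, Peff
    in 1e-4 cm/s for the default config).
    """

    slope: float
    intercept: float
    papp_unit: float = 1e-6  # cm/s per table unit
    peff_unit: float = 1e-4  # cm/s per regression output unit

    @classmethod
    def default(cls) -> "SunRegression":
        with resources.as_file(
            resources.files("bispbk.data") / "sun_regression.json"
        ) as path:
            cfg = json.loads(path.read_text())
        return cls(slope=cfg["slope"], intercept=cfg["intercept"])


@dataclass
class AbsorptionParams:
    papp_mean: float  # 1e-6 cm/s
    peff: float  # 1e-4 cm/s
    ka: float  # 1/h

    def __post_init__(self) -> None:
        if not (self.papp_mean > 0 and self.peff > 0 and self.ka > 0):
            raise ValueError("absorption parameters must all be positive")


def aggregate_papp(spec: ChemicalSpec) -> float:
    """Mean Papp (1e-6 cm/s) over in vitro and QSAR sources, equal weight."""
    values = spec.papp_list()
    if not values:
        raise ValueError(f"{spec.name}: no Papp values available")
    return average_property(values)


def papp_to_peff(papp_mean: float, regression: SunRegression | None = None) -> float:
    """Effective permeability (1e-4 cm/s) from mean Papp (1e-6 cm/s)."""
    if not papp_mean > 0:
        raise ValueError(f"Papp must be positive, got {papp_mean}")
    reg = regression or SunRegression.default()
    return 10.0 ** (reg.slope * math.log10(papp_mean) + reg.intercept)


def peff_to_ka(peff: float, intestinal_radius: float) -> float:
    """First-order uptake rate (1/h) from Peff (1e-4 cm/s) and radius (cm).

    Cylindrical-lumen surface-to-volume relation: ka = 2*Peff/R, converted
    from 1/s to 1/h.
    """
    if peff < 0:
        raise ValueError(f"Peff must be non-negative, got {peff}")
    if not intestinal_radius > 0:
        raise ValueError(f"intestinal radius must be positive, got {intestinal_radius}")
    peff_cm_s = peff * 1e-4
    return 2.0 * peff_cm_s / intestinal_radius * 3600.0


def parametrize_absorption(
    spec: ChemicalSpec,
    intestinal_radius: float,
    regression: SunRegression | None = None,
) -> AbsorptionParams:
    """Full chain Papp -> Peff -> ka for one chemical and one physiology."""
    papp = aggregate_papp(spec)
    peff = papp_to_peff(papp, regression)
    return AbsorptionParams(papp, peff, peff_to_ka(peff, intestinal_radius))
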