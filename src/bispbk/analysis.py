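"""Model-evaluation diagnostics: mass balance, clearances, 2-fold checks.

Mass-balance analysis reports the fractions of the administered dose excreted
via urine and feces at checkpoint times (parent-equivalent moles, so
conjugation cannot break the balance). Renal clearance is computed per
analyte as cumulative urinary amount over blood AUC (0-24 h), biliary
clearance as hepatic blood flow times EHCr; the bile-to-plasma concentration
ratio divides biliary clearance by the daily bile flow, and the apparent
fraction absorbed multiplies total clearance by the blood AUC over the oral
dose (values above 1 indicate extensive enterohepatic recirculation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PBKParameters, SimulationResult

__all__ = [
    "MassBalanceReport",
    "ClearanceReport",
    "mass_balance",
    "renal_clearance",
    "biliary_clearance",
    "clearance_report",
    "two_fold_evaluation",
    "evaluation_breakdowns",
    "load_observed_tk",
]


@dataclass
class MassBalanceReport:
    checkpoints: tuple  # h
    urinary_pct: tuple  # % of dose, parent + glucuronide, parent-equivalents
    fecal_pct: tuple  # % of dose
    retained_pct: tuple  # % of dose still in the body
    urinary_parent_pct: tuple  # % of dose excreted unconjugated

    def __post_init__(self) -> None:
        for u, f, r in zip(self.urinary_pct, self.fecal_pct, self.retained_pct):
            if not (-1e-6 <= u <= 100 + 1e-6 and -1e-6 <= f <= 100 + 1e-6):
                raise ValueError("excretion fractions must lie in [0, 100]%")
            if abs(u + f + r - 100.0) > 0.1:
                raise ValueError(
                    f"balance violated: urine {u} + feces {f} + retained {r} != 100"
                )


@dataclass
class ClearanceReport:
    cl_r: float  # L/h
    cl_bile: float  # L/h
    ratio_bile_renal: float
    bile_to_plasma: float
    f_app: float

    def __post_init__(self) -> None:
        vals = (self.cl_r, self.cl_bile, self.ratio_bile_renal, self.bile_to_plasma, self.f_app)
        if any(v < 0 for v in vals):
            raise ValueError("clearance quantities must be non-negative")


def _interp(t, series, checkpoint):
    return float(np.interp(checkpoint, t, series))


def mass_balance(result: SimulationResult, checkpoints=(12.0, 24.0, 48.0)) -> MassBalanceReport:
    """Excreted dose fractions (%) at checkpoint times."""
    t = result.time
    for cp in checkpoints:
        if cp < t[0] - 1e-9 or cp > t[-1] + 1e-9:
            raise ValueError(f"checkpoint {cp} h outside simulation window")
    dose = result.administered
    urinary, fecal, retained, parent_only = [], [], [], []
    total_in = sum(result.amounts.values())
    for cp in checkpoints:
        u_p = _interp(t, result.urine["parent"], cp)
        u_g = _interp(t, result.urine["glucuronide"], cp)
        f = _interp(t, result.feces, cp)
        body = _interp(t, total_in, cp)
        urinary.append(100.0 * (u_p + u_g) / dose)
        fecal.append(100.0 * f / dose)
        retained.append(100.0 * body / dose)
        parent_only.append(100.0 * u_p / dose)
    return MassBalanceReport(
        checkpoints=tuple(checkpoints),
        urinary_pct=tuple(urinary),
        fecal_pct=tuple(fecal),
        retained_pct=tuple(retained),
        urinary_parent_pct=tuple(parent_only),
    )


def renal_clearance(result: SimulationResult, window: float = 24.0) -> float:
    """Total renal clearance, L/h: sum over analytes of urinary amount / AUC.

    Parent clearance results from filtration, glucuronide clearance from
    filtration plus secretion; each analyte's clearance is its cumulative
    urinary excretion over the window divided by its blood AUC (nM*h) over
    the same window, yielding L/h.
    """
    t = result.time
    mask = t <= window + 1e-9
    cl = 0.0
    any_auc = False
    for analyte in ("parent", "glucuronide"):
        conc = result.concentration(analyte, "blood")[mask]
        auc = float(np.trapezoid(conc, t[mask]))  # nM*h = nmol*h/L
        excreted = _interp(t, result.urine[analyte], window)
        if auc <= 0:
            if excreted > 0:
                raise ValueError(f"zero blood AUC with nonzero {analyte} excretion")
            continue
        any_auc = True
        cl += excreted / auc
    if not any_auc:
        raise ValueError("zero blood AUC for both analytes; clearance undefined")
    return cl


def biliary_clearance(params: PBKParameters) -> tuple[float, float]:
    """(CL_bile, bile-to-plasma ratio): QL*EHCr and CL_bile / daily bile flow.

    QL is the liver blood-flow parameter (the liver's direct arterial
    supply; portal inflow reaches the liver via the gut compartment and is
    not part of QL). The bile-to-plasma concentration ratio converts
    CL_bile to L/day before dividing by the bile flow.
    """
    phys = params.physiology
    if not phys.bile_flow > 0:
        raise ValueError("bile flow must be positive")
    ql = phys.flow("liver")
    cl_bile = ql * params.ehcr
    return cl_bile, cl_bile * 24.0 / phys.bile_flow


def clearance_report(result: SimulationResult, window: float = 24.0) -> ClearanceReport:
    """Full clearance diagnostics for a single-dose simulation."""
    params = result.params
    cl_r = renal_clearance(result, window)
    cl_bile, bile_to_plasma = biliary_clearance(params)
    t = result.time
    mask = t <= window + 1e-9
    auc_parent = float(np.trapezoid(result.concentration("parent", "blood")[mask], t[mask]))
    f_app = (cl_r + cl_bile) * auc_parent / result.administered
    return ClearanceReport(
        cl_r=cl_r,
        cl_bile=cl_bile,
        ratio_bile_renal=cl_bile / cl_r if cl_r > 0 else float("inf"),
        bile_to_plasma=bile_to_plasma,
        f_app=f_app,
    )


def two_fold_evaluation(predicted: dict, observed: dict) -> dict:
    """Predicted/observed ratios and the fraction within 2-fold.

    Both inputs map a key (chemical, analyte, metric) - any hashable key -
    to a value. A prediction is "within 2-fold" iff the ratio lies in
    [0.5, 2.0] inclusive. Returns per-key ratios, the within flags, and the
    summary fraction.
    """
    if set(predicted) != set(observed):
        raise ValueError(
            f"key mismatch: {sorted(set(predicted) ^ set(observed), key=str)}"
        )
    if not predicted:
        raise ValueError("no metric pairs to evaluate")
    ratios = {}
    within = {}
    for key, pred in predicted.items():
        obs = observed[key]
        if obs <= 0:
            raise ValueError(f"observed value for {key} must be positive")
        r = pred / obs
        ratios[key] = r
        within[key] = 0.5 <= r <= 2.0
    frac = sum(within.values()) / len(within)
    return {"ratios": ratios, "within": within, "fraction_within": frac}


def load_observed_tk():
    """Packaged observed/predicted blood TK metric table (BPA and BPS)."""
    from importlib import resources

    import pandas as pd

    with resources.as_file(resources.files("bispbk.data") / "observed_tk.csv") as path:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)


def evaluation_breakdowns(table=None) -> dict:
    """Within-2-fold fractions under both denominator conventions.

    The summary fraction of predictions within 2-fold of observation depends
    on whether only human comparisons or human plus rat comparisons are
    counted; both are reported rather than asserting one convention.
    """
    df = load_observed_tk() if table is None else table
    out = {}
    subsets = {
        "human_only": df[df["species"] == "human"],
        "human_and_rat": df,
    }
    for name, sub in subsets.items():
        if sub.empty:
            out[name] = float("nan")
            continue
        keys = [tuple(r) for r in sub[["species", "chemical", "analyte", "metric"]].to_numpy()]
        pred = dict(zip(keys, sub["predicted"]))
        obs = dict(zip(keys, sub["observed"]))
        out[name] = two_fold_evaluation(pred, obs)["fraction_within"]
    return out
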