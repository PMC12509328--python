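"""Two-layer (parent + glucuronide) compartmental PBK model.

Flow-limited perfusion ODE system over stomach, gut lumen, gut wall, liver,
kidney, blood, slowly and rapidly perfused tissues, plus thyroid and gonadal
(testes/breasts) compartments in human physiologies. Oral doses enter the
stomach and empty first-order into the absorbing gut lumen; the parent is
taken up at ka into the gut wall, drains portally into the liver and is
glucuronidated there at a saturable, ontogeny-scaled rate. Glucuronide
leaving the liver splits: a fraction EHCr is excreted via bile into the gut
lumen - assumed immediate and complete - where it reverts to the parent and
becomes absorbable again (enterohepatic circulation); the remainder enters
systemic circulation. The parent is renally filtered (GFR * fu); the
glucuronide is filtered and additionally secreted with a flux
QK * EHCr * (V_kidney / V_liver) from blood, reusing EHCr as a surrogate for
efflux-transporter activity scaled to the renal context. Unabsorbed and
biliary-recycled luminal material exits to feces with a first-order colonic
transit rate.

Units: amounts nmol, volumes L, flows L/h, time h, concentrations nM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .absorption import AbsorptionParams
from .chem import ChemicalSpec
from .kinetics import KineticFit
from .partition import PartitionSet
from .physiology import Physiology

__all__ = [
    "PBKParameters",
    "DoseSchedule",
    "SimulationResult",
    "TKMetrics",
    "SolverConfig",
    "build_parameters",
    "simulate",
    "extract_tk_metrics",
    "make_schedule",
    "REPEATED_DOSE_TIMES",
]

#: Thrice-daily meal times for the repeated-dose scheme, h.
REPEATED_DOSE_TIMES = (0, 6, 12, 24, 30, 36, 48, 56, 60, 72, 78, 84)

_DOSE_UNIT_TO_NG = {"ng_per_kg": 1.0, "ug_per_kg": 1e3, "mg_per_kg": 1e6}


@dataclass
class PBKParameters:
    """Fully resolved parameter bundle for one (chemical, physiology) pair."""

    chemical: ChemicalSpec
    physiology: Physiology
    absorption: AbsorptionParams
    partition: PartitionSet
    kinetics: KineticFit
    ehcr: float
    ktransit: float = 0.05  # 1/h, luminal-to-fecal whole-gut transit (t1/2 ~ 14 h)

    def __post_init__(self) -> None:
        if not 0 <= self.ehcr <= 1:
            raise ValueError(f"EHCr must lie in [0, 1], got {self.ehcr}")
        if self.ktransit < 0:
            raise ValueError("fecal transit rate must be non-negative")

    def kp_organ(self, organ: str) -> str:
        """Map a physiology compartment to its Kp table key."""
        if organ == "gonad":
            return "breast" if self.physiology.sex == "female" else "testes"
        return organ

    def replace(self, **kw) -> "PBKParameters":
        return replace(self, **kw)


@dataclass
class DoseSchedule:
    dose_per_event: float  # in dose_unit per kg bw
    dose_unit: str  # ng_per_kg | ug_per_kg | mg_per_kg
    event_times: tuple  # h
    duration: float  # h

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.event_times)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")
        if self.dose_unit not in _DOSE_UNIT_TO_NG:
            raise ValueError(f"unknown dose unit {self.dose_unit!r}")
        self.event_times = times

    def dose_nmol(self, bw: float, mw_parent: float) -> float:
        """Moles administered per event for a body weight and molar mass."""
        ng = self.dose_per_event * _DOSE_UNIT_TO_NG[self.dose_unit] * bw
        return ng / mw_parent  # ng / (g/mol) = nmol


@dataclass
class SolverConfig:
    rtol: float = 1e-8
    atol_scale: float = 1e-10  # absolute tolerance per nmol of dose
    dt_out: float = 0.01  # output grid spacing, h
    method: str = "LSODA"


@dataclass
class SimulationResult:
    time: np.ndarray  # h
    amounts: dict  # (analyte, compartment) -> nmol array
    volumes: dict  # compartment -> L
    urine: dict  # analyte -> cumulative nmol
    feces: np.ndarray  # cumulative parent nmol
    bile: np.ndarray  # cumulative glucuronide nmol routed via bile
    administered: float  # total nmol dosed by each time point (array)
    administered_t: np.ndarray = field(default=None)
    params: PBKParameters = None

    def concentration(self, analyte: str, compartment: str) -> np.ndarray:
        """Concentration trace in nM for a distributional compartment."""
        return self.amounts[(analyte, compartment)] / self.volumes[compartment]

    def total_in_system(self) -> np.ndarray:
        tot = sum(self.amounts.values())
        return tot + self.urine["parent"] + self.urine["glucuronide"] + self.feces

    def mass_balance_error(self) -> float:
        """Max relative molar-balance error over the whole time grid."""
        denom = np.maximum(self.administered_t, 1e-12)
        with np.errstate(invalid="ignore"):
            err = np.abs(self.total_in_system() - self.administered_t) / denom
        err[self.administered_t <= 0] = np.abs(
            self.total_in_system()[self.administered_t <= 0]
        )
        return float(np.max(err))


@dataclass
class TKMetrics:
    compartment: str
    analyte: str
    cmax: float  # nM
    tmax: float  # h
    auc: float  # nM * day


def build_parameters(
    chemical: ChemicalSpec,
    physiology: Physiology,
    absorption: AbsorptionParams,
    partition: PartitionSet,
    kinetics: KineticFit,
    ehcr: float,
    ktransit: float = 0.05,
) -> PBKParameters:
    """Assemble and validate a simulation-ready parameter bundle."""
    missing = []
    if kinetics.scaled_vmax_liver is None:
        missing.append("whole-liver scaled Vmax (run scale_to_liver first)")
    params = PBKParameters(
        chemical, physiology, absorption, partition, kinetics, ehcr, ktransit
    )
    comps = [params.kp_organ(c) for c in physiology.compartments]
    try:
        partition.validate_coverage(comps)
    except ValueError as exc:
        missing.append(str(exc))
    if missing:
        raise ValueError("incomplete PBK parameter bundle: " + "; ".join(missing))
    return params


def _rhs_factory(params: PBKParameters):
    phys = params.physiology
    comps = phys.compartments  # perfused tissues, liver/gut included
    n = len(comps)
    vols = np.array([phys.volume(c) for c in comps])
    flows = np.array([phys.flow(c) for c in comps])
    v_blood = phys.volume("blood")
    # total perfusion equals the sum of compartment flows so that molar
    # balance holds even under perturbed flow fractions
    co = float(flows.sum())
    kp_p = np.array([params.partition.kp("parent", params.kp_organ(c)) for c in comps])
    kp_g = np.array(
        [params.partition.kp("glucuronide", params.kp_organ(c)) for c in comps]
    )
    i_gut = comps.index("gut")
    i_liv = comps.index("liver")
    q_liv_total = flows[i_gut] + flows[i_liv]

    kst = np.log(2.0) / phys.gest
    ka = params.absorption.ka
    ktr = params.ktransit
    ehcr = params.ehcr
    fu_p = params.partition.fu_parent
    fu_g = params.partition.fu_glucuronide
    gfr = phys.gfr
    ksec = phys.flow("kidney") * ehcr * (phys.volume("kidney") / phys.volume("liver"))

    fit = params.kinetics
    vmax_h = fit.scaled_vmax_liver * fit.sfg * 60.0  # nmol/h whole liver
    km_nm = fit.km * 1000.0
    ki_nm = fit.ki * 1000.0 if fit.ki is not None else None

    # state: [stomach, lumen, parent tissues (n), parent blood,
    #         gluc tissues (n), gluc blood, U_p, U_g, F, B]
    nstate = 2 + 2 * (n + 1) + 4

    def rhs(t, y):
        dy = np.zeros(nstate)
        a_st, a_lu = y[0], y[1]
        ap = y[2 : 2 + n]
        ap_bl = y[2 + n]
        ag = y[3 + n : 3 + 2 * n]
        ag_bl = y[3 + 2 * n]

        cp = ap / vols
        cg = ag / vols
        cbl_p = ap_bl / v_blood
        cbl_g = ag_bl / v_blood
        ven_p = flows * cp / kp_p
        ven_g = flows * cg / kp_g

        # saturable hepatic glucuronidation on liver venous parent conc
        s = cp[i_liv] / kp_p[i_liv]
        if ki_nm is None:
            v_met = vmax_h * s / (km_nm + s)
        else:
            v_met = vmax_h * s / (km_nm + s * (1.0 + s / ki_nm))

        out_liv_g = q_liv_total * cg[i_liv] / kp_g[i_liv]
        bile = ehcr * out_liv_g

        dy[0] = -kst * a_st
        dy[1] = kst * a_st + bile - (ka + ktr) * a_lu

        # parent tissues
        dp = flows * cbl_p - ven_p
        dp[i_gut] += ka * a_lu
        dp[i_liv] = (
            flows[i_liv] * cbl_p
            + ven_p[i_gut]
            - q_liv_total * cp[i_liv] / kp_p[i_liv]
            - v_met
        )
        dy[2 : 2 + n] = dp
        ven_to_blood_p = ven_p.sum() - ven_p[i_gut] - ven_p[i_liv]
        dy[2 + n] = (
            ven_to_blood_p
            + q_liv_total * cp[i_liv] / kp_p[i_liv]
            - co * cbl_p
            - gfr * fu_p * cbl_p
        )

        # glucuronide tissues
        dg = flows * cbl_g - ven_g
        dg[i_liv] = (
            flows[i_liv] * cbl_g + ven_g[i_gut] - out_liv_g + v_met
        )
        dy[3 + n : 3 + 2 * n] = dg
        ven_to_blood_g = ven_g.sum() - ven_g[i_gut] - ven_g[i_liv]
        renal_g = (gfr * fu_g + ksec) * cbl_g
        dy[3 + 2 * n] = (
            ven_to_blood_g + (1.0 - ehcr) * out_liv_g - co * cbl_g - renal_g
        )

        dy[4 + 2 * n] = gfr * fu_p * cbl_p  # urine, parent
        dy[5 + 2 * n] = renal_g  # urine, glucuronide
        dy[6 + 2 * n] = ktr * a_lu  # feces
        dy[7 + 2 * n] = bile  # cumulative biliary transfer
        return dy

    return rhs, nstate, comps, vols, v_blood


def simulate(
    params: PBKParameters,
    schedule: DoseSchedule,
    solver: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate the PBK system over a dose schedule.

    Dose events are exact discontinuities: integration restarts at each event
    with the dose added to the stomach compartment.
    """
    solver = solver or SolverConfig()
    rhs, nstate, comps, vols, v_blood = _rhs_factory(params)
    dose = schedule.dose_nmol(params.physiology.bw, params.chemical.mw_parent)

    n_out = int(round(schedule.duration / solver.dt_out)) + 1
    t_grid = np.linspace(0.0, schedule.duration, n_out)
    atol = solver.atol_scale * max(dose * len(schedule.event_times), 1.0)

    y = np.zeros(nstate)
    traj = np.zeros((nstate, n_out))
    admin = np.zeros(n_out)
    total_given = 0.0
    # piecewise integration between consecutive event times
    seg_bounds = sorted(set([0.0, schedule.duration] + list(schedule.event_times)))
    for t0, t1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        if t0 in schedule.event_times:
            y[0] += dose
            total_given += dose
        mask = (t_grid >= t0 - 1e-12) & (t_grid <= t1 + 1e-12)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=solver.method,
            t_eval=t_eval if t_eval.size else None,
            rtol=solver.rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{t0}, {t1}]: {sol.message}")
        if t_eval.size:
            idx = np.where(mask)[0]
            traj[:, idx] = sol.y
            admin[idx] = total_given
        y = sol.y[:, -1].copy()

    if traj.min() < -atol * 1e3:
        raise RuntimeError(
            f"negative state encountered (min {traj.min():.3e}); "
            "tighten solver tolerances"
        )
    traj = np.clip(traj, 0.0, None)

    n = len(comps)
    amounts = {("parent", "stomach"): traj[0], ("parent", "lumen"): traj[1]}
    volumes = {c: v for c, v in zip(comps, vols)}
    volumes["blood"] = v_blood
    for i, c in enumerate(comps):
        amounts[("parent", c)] = traj[2 + i]
        amounts[("glucuronide", c)] = traj[3 + n + i]
    amounts[("parent", "blood")] = traj[2 + n]
    amounts[("glucuronide", "blood")] = traj[3 + 2 * n]

    return SimulationResult(
        time=t_grid,
        amounts=amounts,
        volumes=volumes,
        urine={"parent": traj[4 + 2 * n], "glucuronide": traj[5 + 2 * n]},
        feces=traj[6 + 2 * n],
        bile=traj[7 + 2 * n],
        administered=total_given,
        administered_t=admin,
        params=params,
    )


def extract_tk_metrics(
    result: SimulationResult, compartment: str, analyte: str = "parent"
) -> TKMetrics:
    """Cmax / tmax / AUC for one compartment and analyte.

    tmax is the earliest grid time attaining the maximum; AUC is trapezoidal
    over the full simulation window, reported in nM*day.
    """
    if (analyte, compartment) not in result.amounts or compartment not in result.volumes:
        raise KeyError(f"unknown compartment {compartment!r} for {analyte!r}")
    conc = result.concentration(analyte, compartment)
    i_max = int(np.argmax(conc))
    auc_nm_h = float(np.trapezoid(conc, result.time))
    return TKMetrics(
        compartment=compartment,
        analyte=analyte,
        cmax=float(conc[i_max]),
        tmax=float(result.time[i_max]),
        auc=auc_nm_h / 24.0,
    )


def _scenario_table() -> pd.DataFrame:
    with resources.as_file(resources.files("bispbk.data") / "scenarios.csv") as path:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)


def make_schedule(scenario: int, alt_dose: float | None = None) -> DoseSchedule:
    """Dose schedule for one of the twelve packaged exposure scenarios.

    ``alt_dose`` overrides the tabulated per-event dose (same unit), e.g. the
    alternative 8.75 ug/kg reading of the BPS evaluation scenario.
    """
    table = _scenario_table()
    row = table[table["scenario"] == scenario]
    if row.empty:
        raise ValueError(f"unknown scenario {scenario!r} (valid: 1-12)")
    row = row.iloc[0]
    times = REPEATED_DOSE_TIMES if row["schedule"] == "repeated" else (0.0,)
    return DoseSchedule(
        dose_per_event=float(alt_dose if alt_dose is not None else row["dose"]),
        dose_unit=row["dose_unit"],
        event_times=times,
        duration=float(row["duration_h"]),
    )


def scenario_info(scenario: int) -> dict:
    """Model label and chemical(s) for a scenario, from the packaged table."""
    table = _scenario_table()
    row = table[table["scenario"] == scenario]
    if row.empty:
        raise ValueError(f"unknown scenario {scenario!r}")
    row = row.iloc[0]
    return {
        "model": row["model"],
        "chemical": row["chemical"],
        "purpose": row["purpose"],
    }
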