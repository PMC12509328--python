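"""Local and global sensitivity analysis and Monte Carlo uncertainty.

Local coefficients are normalized forward differences. Global analysis
follows the screen-then-quantify workflow: Morris elementary-effects
screening over all parameters, then an eFAST variance decomposition
(first-order and total-order indices) on the selected subset; both engines
are implemented here as generic samplers over a scalar function of a unit
hypercube and validated against analytic test functions. Monte Carlo
uncertainty propagation resamples the sensitive parameters from configured
distributions, projects every draw onto the physiological constraints (EHCr
clipped to [0, 1]; organ-weight and blood-flow fraction vectors renormalized
to their baseline sums), simulates, and summarizes concentrations per time
point by first quartile, median and third quartile.

Parameters are addressed by dotted paths, e.g. ``bw``, ``ehcr``, ``vmax``,
``vol_frac.liver``, ``flow_frac.slow``, ``kp_parent.liver``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DoseSchedule,
    PBKParameters,
    SimulationResult,
    SolverConfig,
    simulate,
)

__all__ = [
    "get_param",
    "apply_params",
    "local_sensitivity",
    "morris_engine",
    "efast_engine",
    "morris_screen",
    "efast",
    "monte_carlo",
    "MCSummary",
]

_SCALARS = {
    "bw": ("physiology", "bw"),
    "cardiac_output": ("physiology", "cardiac_output"),
    "gest": ("physiology", "gest"),
    "gfr": ("physiology", "gfr"),
    "bile_flow": ("physiology", "bile_flow"),
    "ka": ("absorption", "ka"),
    "fu_parent": ("partition", "fu_parent"),
    "fu_glucuronide": ("partition", "fu_glucuronide"),
    "vmax": ("kinetics", "scaled_vmax_liver"),
    "km": ("kinetics", "km"),
    "ki": ("kinetics", "ki"),
    "sfg": ("kinetics", "sfg"),
    "ehcr": (None, "ehcr"),
    "ktransit": (None, "ktransit"),
}


def get_param(params: PBKParameters, path: str) -> float:
    """Baseline value of a dotted parameter path."""
    if "." in path:
        group, key = path.split(".", 1)
        if group in ("vol_frac", "flow_frac"):
            return getattr(params.physiology, group)[key]
        if group in ("kp_parent", "kp_glucuronide"):
            return getattr(params.partition, group)[key]
        raise KeyError(f"unknown parameter group {group!r}")
    if path not in _SCALARS:
        raise KeyError(f"unknown parameter {path!r}")
    owner, attr = _SCALARS[path]
    obj = params if owner is None else getattr(params, owner)
    return getattr(obj, attr)


def apply_params(params: PBKParameters, updates: dict) -> PBKParameters:
    """New parameter bundle with the given path -> value updates applied.

    Mutation happens on a deep copy and bypasses construction-time
    validation, which is what allows constrained projections to restore
    invariants afterwards.
    """
    new = copy.deepcopy(params)
    for path, value in updates.items():
        if "." in path:
            group, key = path.split(".", 1)
            if group in ("vol_frac", "flow_frac"):
                getattr(new.physiology, group)[key] = float(value)
            elif group in ("kp_parent", "kp_glucuronide"):
                getattr(new.partition, group)[key] = float(value)
            else:
                raise KeyError(f"unknown parameter group {group!r}")
        else:
            owner, attr = _SCALARS[path]
            obj = new if owner is None else getattr(new, owner)
            setattr(obj, attr, float(value))
    return new


def local_sensitivity(
    params: PBKParameters,
    schedule: DoseSchedule,
    parameter: str,
    output_fn,
    rel_step: float = 0.01,
    central: bool = False,
    solver: SolverConfig | None = None,
) -> float:
    """Normalized local sensitivity coefficient (dY/Y)/(dp/p).

    ``output_fn`` maps a SimulationResult to a scalar (e.g. blood Cmax).
    Parameters with |coefficient| > 0.1 are conventionally called sensitive.
    """
    solver = solver or SolverConfig(dt_out=0.02)
    p0 = get_param(params, parameter)
    if p0 == 0:
        raise ValueError(f"cannot perturb parameter {parameter!r} with value 0")
    y0 = output_fn(simulate(params, schedule, solver))
    if y0 == 0:
        raise ValueError("baseline output is 0; coefficient undefined")
    y_hi = output_fn(
        simulate(apply_params(params, {parameter: p0 * (1 + rel_step)}), schedule, solver)
    )
    if central:
        y_lo = output_fn(
            simulate(apply_params(params, {parameter: p0 * (1 - rel_step)}), schedule, solver)
        )
        return (y_hi - y_lo) / y0 / (2 * rel_step)
    return (y_hi - y0) / y0 / rel_step


# ---------------------------------------------------------------------------
# generic GSA engines on the unit hypercube


def morris_engine(func, names, lows, highs, trajectories=10, levels=4, seed=0):
    """Morris elementary-effects screening.

    Radial trajectories on a ``levels``-level grid with step
    delta = levels / (2 (levels - 1)) on the unit cube, mapped linearly to
    [low, high] per parameter. Returns {name: (mu_star, sigma)}.
    """
    rng = np.random.default_rng(seed)
    k = len(names)
    lows = np.asarray(lows, float)
    highs = np.asarray(highs, float)
    keep = highs > lows
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(0, levels // 2) / (levels - 1)  # start levels that allow +delta

    effects = {name: [] for name in names}
    for _ in range(trajectories):
        x = rng.choice(grid, size=k)
        order = rng.permutation(k)
        y_prev = func(lows + x * (highs - lows))
        for i in order:
            if not keep[i]:
                continue
            x_new = x.copy()
            x_new[i] = x[i] + delta
            y_new = func(lows + x_new * (highs - lows))
            effects[names[i]].append((y_new - y_prev) / delta)
            x, y_prev = x_new, y_new
    out = {}
    for name, idx in zip(names, range(k)):
        ee = np.asarray(effects[name], float)
        if ee.size == 0:
            out[name] = (0.0, 0.0)  # degenerate range: parameter skipped
        else:
            out[name] = (
                float(np.mean(np.abs(ee))),
                float(np.std(ee, ddof=1)) if ee.size > 1 else 0.0,
            )
    return out


def efast_engine(func, names, lows, highs, n_samples=257, interference=4, seed=0):
    """Extended FAST first-order and total-order indices.

    One search curve per parameter: the parameter of interest is driven at
    the maximal frequency (N-1)/(2M); complementary parameters share low
    frequencies up to max(1, w_max/(2M)). Indices derive from the Fourier
    spectrum of the model output along the curve. Returns
    {name: (first_order, total_order)}.
    """
    k = len(names)
    if k < 2:
        raise ValueError("eFAST needs at least 2 parameters")
    m = interference
    n = int(n_samples)
    if n % 2 == 0:
        n += 1
    w_max = (n - 1) // (2 * m)
    if w_max < 4:
        raise ValueError(f"n_samples={n_samples} too small for eFAST (need >= {8 * m + 1})")
    w_comp_max = max(1, w_max // (2 * m))
    rng = np.random.default_rng(seed)
    lows = np.asarray(lows, float)
    highs = np.asarray(highs, float)

    s = np.pi * (2.0 * np.arange(n) + 1.0 - n) / n
    out = {}
    for i in range(k):
        freqs = np.empty(k)
        freqs[i] = w_max
        others = [j for j in range(k) if j != i]
        for rank, j in enumerate(others):
            freqs[j] = 1 + (rank % w_comp_max)
        phase = rng.uniform(0, 2 * np.pi, size=k)
        x = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phase[None, :])) / np.pi
        xs = lows[None, :] + x * (highs - lows)[None, :]
        y = np.array([func(row) for row in xs], float)

        max_harm = (n - 1) // 2
        r = np.arange(1, max_harm + 1)
        cosr = np.cos(np.outer(r, s))
        sinr = np.sin(np.outer(r, s))
        a = cosr @ y / n
        b = sinr @ y / n
        spectrum = 2.0 * (a**2 + b**2)
        total_var = float(spectrum.sum())
        if total_var <= 0:
            out[names[i]] = (0.0, 0.0)
            continue
        harmonics = np.arange(1, m + 1) * w_max
        harmonics = harmonics[harmonics <= max_harm]
        d_i = float(spectrum[harmonics - 1].sum())
        d_comp = float(spectrum[: w_max // 2].sum())
        out[names[i]] = (d_i / total_var, max(0.0, 1.0 - d_comp / total_var))
    return out


# ---------------------------------------------------------------------------
# PBK model wrappers


def _output_fn_auc(analyte="parent", compartment="blood", window=4.0):
    def fn(result: SimulationResult):
        mask = result.time <= window + 1e-9
        conc = result.concentration(analyte, compartment)[mask]
        return float(np.trapezoid(conc, result.time[mask]))

    return fn


def _ranges_from_cv(params, parameters, cvs, n_sd=2.0):
    names, lows, highs = [], [], []
    for p in parameters:
        val = get_param(params, p)
        cv = cvs.get(p, 0.2)
        lo = max(val * (1 - n_sd * cv), 1e-12)
        hi = val * (1 + n_sd * cv)
        if p == "ehcr":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        names.append(p)
        lows.append(lo)
        highs.append(hi)
    return names, np.array(lows), np.array(highs)


def _model_func(params, schedule, names, output_fn, solver):
    def func(x):
        updates = dict(zip(names, x))
        if "ehcr" in updates:
            updates["ehcr"] = float(np.clip(updates["ehcr"], 0.0, 1.0))
        res = simulate(apply_params(params, updates), schedule, solver)
        return output_fn(res)

    return func


def morris_screen(
    params,
    schedule,
    parameters,
    cvs,
    output_fn=None,
    trajectories=10,
    levels=4,
    seed=0,
    solver=None,
):
    """Morris screening of PBK parameters on AUC(0-4 h) by default."""
    solver = solver or SolverConfig(dt_out=0.05)
    output_fn = output_fn or _output_fn_auc()
    names, lows, highs = _ranges_from_cv(params, parameters, cvs)
    func = _model_func(params, schedule, names, output_fn, solver)
    return morris_engine(func, names, lows, highs, trajectories, levels, seed)


def efast(
    params,
    schedule,
    parameters,
    cvs,
    output_fn=None,
    n_samples=257,
    seed=0,
    solver=None,
):
    """eFAST variance decomposition of PBK parameters on AUC(0-4 h)."""
    if len(parameters) < 2:
        raise ValueError("eFAST needs at least 2 selected parameters")
    solver = solver or SolverConfig(dt_out=0.05)
    output_fn = output_fn or _output_fn_auc()
    names, lows, highs = _ranges_from_cv(params, parameters, cvs)
    func = _model_func(params, schedule, names, output_fn, solver)
    return efast_engine(func, names, lows, highs, n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty propagation


@dataclass
class MCSummary:
    time: np.ndarray
    q1: dict  # (analyte, compartment) -> array
    median: dict
    q3: dict
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        for key in self.median:
            if not (
                np.all(self.q1[key] <= self.median[key] + 1e-12)
                and np.all(self.median[key] <= self.q3[key] + 1e-12)
            ):
                raise ValueError(f"quartile ordering violated for {key}")


def _draw(rng, family, baseline, cv):
    if cv == 0:
        return baseline
    if family == "normal":
        return baseline * (1.0 + cv * rng.standard_normal())
    if family == "lognormal":
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return baseline * math.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma)
    if family == "uniform":
        half = math.sqrt(3.0) * cv
        return baseline * rng.uniform(1.0 - half, 1.0 + half)
    raise ValueError(f"unknown distribution family {family!r}")


def _project_constraints(params: PBKParameters, updated: PBKParameters) -> PBKParameters:
    """Restore the physiological sum constraints after sampling.

    EHCr is clipped to [0, 1]; the organ-volume and blood-flow fraction
    vectors are renormalized multiplicatively to the baseline sums.
    """
    updated.ehcr = float(np.clip(updated.ehcr, 0.0, 1.0))
    for group in ("vol_frac", "flow_frac"):
        base = getattr(params.physiology, group)
        cur = getattr(updated.physiology, group)
        target = sum(base.values())
        total = sum(cur.values())
        if total > 0 and abs(total - target) > 1e-12:
            scale = target / total
            for key in cur:
                cur[key] *= scale
    return updated


def monte_carlo(
    params: PBKParameters,
    schedule: DoseSchedule,
    distributions,
    n_draws: int,
    seed: int,
    outputs=(("parent", "blood"), ("glucuronide", "blood")),
    solver: SolverConfig | None = None,
    return_draws: bool = False,
):
    """Constrained Monte Carlo propagation of parameter uncertainty.

    ``distributions`` is an iterable of (parameter_path, family, cv). Every
    draw is projected onto the constraints before simulation. Concentration
    traces are summarized per time point by Q1/median/Q3.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    dist = [(p, fam, float(cv)) for p, fam, cv in distributions]
    for _, fam, cv in dist:
        if fam not in ("normal", "lognormal", "uniform"):
            raise ValueError(f"unknown distribution family {fam!r}")
        if cv < 0:
            raise ValueError("CV must be non-negative")
    solver = solver or SolverConfig(dt_out=0.05)
    rng = np.random.default_rng(seed)
    baselines = {p: get_param(params, p) for p, _, _ in dist}

    traces = {key: [] for key in outputs}
    draws = []
    time = None
    for _ in range(n_draws):
        updates = {}
        for p, fam, cv in dist:
            val = _draw(rng, fam, baselines[p], cv)
            updates[p] = max(val, 1e-12)
        candidate = _project_constraints(params, apply_params(params, updates))
        draws.append(candidate)
        res = simulate(candidate, schedule, solver)
        time = res.time
        for key in outputs:
            traces[key].append(res.concentration(*key))

    q1, med, q3 = {}, {}, {}
    for key in outputs:
        arr = np.vstack(traces[key])
        q1[key] = np.quantile(arr, 0.25, axis=0)
        med[key] = np.quantile(arr, 0.5, axis=0)
        q3[key] = np.quantile(arr, 0.75, axis=0)
    summary = MCSummary(time=time, q1=q1, median=med, q3=q3, n_draws=n_draws, seed=seed)
    if return_draws:
        return summary, draws
    return summary


def load_variability_table(source=None):
    """(parameter, family, cv) triples from a delimited variability table."""
    import pandas as pd
    from importlib import resources

    if source is None:
        with resources.as_file(
            resources.files("bispbk.data") / "variability_synthetic.csv"
        ) as path:
            df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    else:
        df = pd.read_csv(source, comment="#", skip_blank_lines=True)
    return [(r["parameter"], r["family"], float(r["cv"])) for _, r in df.iterrows()]
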