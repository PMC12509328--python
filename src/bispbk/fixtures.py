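"""Synthetic-data generators for every fit path in the workflow.

Substrate-depletion time courses are integrated from a chosen rate law with
optional multiplicative Gaussian noise; rat blood concentration-time data
are generated from the rat PBK model itself with a known true EHCr. Both
are deterministic under a fixed seed, which makes parameter-recovery tests
exact oracles: the generating parameters are the expected fit results.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    DepletionSeries,
    fit_michaelis_menten,
    fit_substrate_inhibition,
    michaelis_menten_rate,
    select_best_fit,
    substrate_inhibition_rate,
)
from .model import DoseSchedule, PBKParameters, SolverConfig, simulate

__all__ = [
    "generate_depletion_fixture",
    "fit_depletion",
    "generate_rat_timecourse_fixture",
]

#: Default incubation protocol: initial substrate levels (uM) and sampling
#: times (h) chosen so that depletion is measurable at every level.
DEFAULT_S0 = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0)
DEFAULT_TIMES = tuple(m / 60.0 for m in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0))


def generate_depletion_fixture(
    vmax: float,
    km: float,
    ki: float | None = None,
    s0_levels=DEFAULT_S0,
    times=DEFAULT_TIMES,
    protein_conc: float = 1.0,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    system: str = "human_S9",
) -> list[DepletionSeries]:
    """Integrate substrate-depletion curves from a known rate law.

    dC/dt = -v(C) * protein_conc with v in nmol/min/mg and C in uM; noise is
    multiplicative Gaussian with relative sd ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if not (vmax > 0 and km > 0) or (ki is not None and not ki > 0):
        raise ValueError("generating kinetic constants must be positive")
    rng = np.random.default_rng(seed)

    def rate(c):
        if ki is None:
            return michaelis_menten_rate(c, vmax, km)
        return substrate_inhibition_rate(c, vmax, km, ki)

    def rhs(t_min, y):
        return [-float(rate(max(y[0], 0.0))) * protein_conc]

    t_min = np.asarray(times, float) * 60.0
    out = []
    for s0 in s0_levels:
        sol = solve_ivp(
            rhs, (t_min[0], t_min[-1]), [float(s0)], t_eval=t_min,
            rtol=1e-10, atol=1e-12,
        )
        clean = np.clip(sol.y[0], 0.0, None)
        for rep in range(n_replicates):
            noisy = clean * (1.0 + noise_sd * rng.standard_normal(clean.size))
            out.append(
                DepletionSeries(
                    times=np.asarray(times, float),
                    concentrations=np.clip(noisy, 0.0, None),
                    protein_conc=protein_conc,
                    replicate=f"S0={s0}uM_r{rep + 1}",
                    system=system,
                )
            )
    return out


def fit_depletion(series_list, try_substrate_inhibition: bool = True):
    """Pool (S, v) pairs from depletion series and select the best rate law."""
    from .kinetics import depletion_to_rates

    s_all, v_all = [], []
    for series in series_list:
        s, v = depletion_to_rates(series)
        s_all.append(s)
        v_all.append(v)
    s = np.concatenate(s_all)
    v = np.concatenate(v_all)
    system = series_list[0].system
    fits = []
    try:
        fits.append(fit_michaelis_menten(s, v, system=system))
    except (ValueError, RuntimeError):
        pass
    if try_substrate_inhibition:
        try:
            fits.append(fit_substrate_inhibition(s, v, system=system))
        except (ValueError, RuntimeError):
            pass
    return select_best_fit(fits)


def generate_rat_timecourse_fixture(
    params: PBKParameters,
    schedule: DoseSchedule,
    true_ehcr: float,
    sample_times,
    noise_sd: float = 0.0,
    seed: int = 0,
    solver: SolverConfig | None = None,
):
    """Observed-style rat blood data from a simulation with known EHCr.

    Returns (times, concentrations) in h and nM. Sampling times must lie
    within the simulated window.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    sample_times = np.asarray(sample_times, float)
    if sample_times.min() < 0 or sample_times.max() > schedule.duration:
        raise ValueError("sampling times outside the simulation window")
    solver = solver or SolverConfig(dt_out=0.02)
    res = simulate(params.replace(ehcr=float(true_ehcr)), schedule, solver)
    conc = np.interp(sample_times, res.time, res.concentration("parent", "blood"))
    rng = np.random.default_rng(seed)
    noisy = conc * (1.0 + noise_sd * rng.standard_normal(conc.size))
    return sample_times, np.clip(noisy, 0.0, None)
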