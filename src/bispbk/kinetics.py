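"""Hepatic glucuronidation kinetics from in vitro substrate depletion.

Workflow: replicate outlier exclusion (Nalimov test), conversion of depletion
time courses to (substrate, rate) pairs, least-squares fitting of
Michaelis-Menten and substrate-inhibition rate laws, model selection by R^2,
scaling of Vmax to the whole liver by the protein yield of the in vitro
system, and ontogeny scaling of metabolic capacity by UGT2B15 abundance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DepletionSeries",
    "KineticFit",
    "PROTEIN_YIELD",
    "nalimov_filter",
    "depletion_to_rates",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "select_best_fit",
    "scale_to_liver",
    "ontogeny_sfg",
    "michaelis_menten_rate",
    "substrate_inhibition_rate",
]

#: Scalable protein content per in vitro system, mg protein / g liver.
PROTEIN_YIELD = {
    "human_S9": 107.3,
    "rat_S9": 143.0,
    "human_microsome": 32.0,
}


@dataclass
class DepletionSeries:
    """One substrate-depletion incubation time course."""

    times: np.ndarray  # h
    concentrations: np.ndarray  # uM
    protein_conc: float  # mg protein / mL
    replicate: str = "r1"
    system: str = "human_S9"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.protein_conc > 0:
            raise ValueError("protein concentration must be positive")


@dataclass
class KineticFit:
    model: str  # "MM" | "substrate_inhibition"
    vmax: float  # nmol/min/mg protein
    km: float  # uM
    ki: float | None  # uM, substrate inhibition only
    r2: float
    system: str = "human_S9"
    scaled_vmax_liver: float | None = None  # nmol/min whole organ
    sfg: float = 1.0

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.km > 0):
            raise ValueError("Vmax and Km must be positive")
        if self.ki is not None and not self.ki > 0:
            raise ValueError("Ki must be positive when present")
        if not self.sfg > 0:
            raise ValueError("SFg must be positive")

    def rate(self, s):
        """Velocity (nmol/min/mg) at substrate concentration s (uM)."""
        if self.model == "MM":
            return michaelis_menten_rate(s, self.vmax, self.km)
        return substrate_inhibition_rate(s, self.vmax, self.km, self.ki)


def michaelis_menten_rate(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def substrate_inhibition_rate(s, vmax, km, ki):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s * (1.0 + s / ki))


def _nalimov_critical(n: int, alpha: float = 0.05) -> float:
    with resources.as_file(
        resources.files("bispbk.data") / "nalimov_critical.json"
    ) as path:
        table = json.loads(path.read_text())[f"{alpha:g}"]
    sizes = sorted(int(k) for k in table if k != "inf")
    for size in sizes:
        if n <= size:
            return table[str(size)]
    return table["inf"]


def nalimov_filter(values, alpha: float = 0.05):
    """Iterative Nalimov outlier exclusion on replicate measurements.

    The statistic for candidate x in a sample of size n is
    ``q = |x - mean| * sqrt(n / (n - 1)) / sd``; the most extreme value is
    removed while its q exceeds the critical value at ``alpha``, stopping
    when fewer than 3 values would remain. Returns ``(retained, excluded)``
    where ``excluded`` holds indices into the original sequence.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("Nalimov test requires at least 3 values")
    idx = list(range(vals.size))
    excluded: list[int] = []
    while len(idx) >= 3:
        sub = vals[idx]
        n = sub.size
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        q = np.abs(sub - sub.mean()) * math.sqrt(n / (n - 1)) / sd
        worst = int(np.argmax(q))
        if q[worst] > _nalimov_critical(n, alpha):
            excluded.append(idx.pop(worst))
        else:
            break
    return vals[idx], sorted(excluded)


def depletion_to_rates(series: DepletionSeries):
    """Glucuronidation rates from compound loss over time.

    Each interval contributes one (S, v) pair: v = -dC/dt normalized by the
    protein concentration (nmol/min/mg), S = interval-mean substrate (uM).
    Negative finite-difference rates (apparent substrate gain, i.e. noise)
    are clipped to zero.
    """
    t, c = series.times, series.concentrations
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    dt_min = np.diff(t) * 60.0  # h -> min
    # uM/min / (mg/mL) = nmol/mL/min / (mg/mL) = nmol/min/mg
    v = np.maximum(-np.diff(c) / dt_min, 0.0) / series.protein_conc
    s = 0.5 * (c[:-1] + c[1:])
    return s, v


def _r2(observed, fitted) -> float:
    observed = np.asarray(observed, float)
    sse = float(np.sum((observed - fitted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else 0.0
    return max(0.0, min(1.0, 1.0 - sse / sst))


def _multistart_fit(func, s, v, p0_list, bounds):
    best = None
    for p0 in p0_list:
        try:
            popt, _ = curve_fit(func, s, v, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((v - func(s, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("kinetic fit did not converge from any start")
    return best[0]


def fit_michaelis_menten(s, v, system: str = "human_S9") -> KineticFit:
    """Least-squares Michaelis-Menten fit of (substrate, rate) pairs."""
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    if np.unique(s).size < 3:
        raise ValueError("need at least 3 distinct substrate levels")
    vmax0 = max(v.max(), 1e-9)
    km0 = max(float(np.median(s)), 1e-9)
    starts = [(vmax0, km0), (2 * vmax0, 5 * km0), (0.5 * vmax0, 0.2 * km0)]
    popt = _multistart_fit(
        michaelis_menten_rate, s, v, starts, bounds=([1e-12, 1e-12], [np.inf, np.inf])
    )
    fitted = michaelis_menten_rate(s, *popt)
    return KineticFit("MM", popt[0], popt[1], None, _r2(v, fitted), system=system)


def fit_substrate_inhibition(s, v, system: str = "human_S9") -> KineticFit:
    """Least-squares substrate-inhibition fit: v = Vmax*S/(Km + S(1+S/Ki))."""
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    if np.unique(s).size < 4:
        raise ValueError("need at least 4 distinct substrate levels")
    vmax0 = max(v.max(), 1e-9)
    km0 = max(float(np.median(s)), 1e-9)
    ki0 = 10.0 * float(s.max())
    starts = [
        (vmax0, km0, ki0),
        (2 * vmax0, 5 * km0, 10 * ki0),
        (0.5 * vmax0, 0.2 * km0, 0.1 * ki0),
    ]
    popt = _multistart_fit(
        substrate_inhibition_rate,
        s,
        v,
        starts,
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
    )
    fitted = substrate_inhibition_rate(s, *popt)
    return KineticFit(
        "substrate_inhibition", popt[0], popt[1], popt[2], _r2(v, fitted), system=system
    )


def select_best_fit(fits) -> KineticFit:
    """Best fit by maximal R^2; ties break toward the simpler MM model."""
    fits = [f for f in fits if f is not None]
    if not fits:
        raise ValueError("no successful fits to select from")
    # sort: higher r2 first; at equal r2 MM (fewer parameters) wins
    order = {"MM": 0, "substrate_inhibition": 1}
    return sorted(fits, key=lambda f: (-f.r2, order.get(f.model, 9)))[0]


def scale_to_liver(
    fit: KineticFit, liver_mass_g: float, protein_yield: float | None = None
) -> KineticFit:
    """Scale per-mg Vmax to the whole organ: Vmax * yield * liver mass.

    The protein yield (mg protein / g liver) defaults to the packaged value
    for the fit's in vitro system; passing a yield that does not match the
    fit's system tag is rejected.
    """
    if not liver_mass_g > 0:
        raise ValueError("liver mass must be positive")
    expected = PROTEIN_YIELD.get(fit.system)
    if protein_yield is None:
        if expected is None:
            raise ValueError(f"unknown in vitro system {fit.system!r}")
        protein_yield = expected
    elif expected is not None and not math.isclose(protein_yield, expected):
        raise ValueError(
            f"protein yield {protein_yield} does not match system "
            f"{fit.system!r} (expected {expected})"
        )
    if not protein_yield > 0:
        raise ValueError("protein yield must be positive")
    fit.scaled_vmax_liver = fit.vmax * protein_yield * liver_mass_g
    return fit


def ontogeny_sfg(abundance_age: float, abundance_adult: float) -> float:
    """UGT2B15 ontogeny scaling factor: age-class / adult protein abundance."""
    if not (abundance_age > 0 and abundance_adult > 0):
        raise ValueError("protein abundances must be positive")
    return abundance_age / abundance_adult
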