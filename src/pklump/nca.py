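"""Non-compartmental analysis of simulated concentration profiles.

Exposure is summarised by the linear trapezoidal AUC to the last grid
point (AUC_last); on the dense grids produced by the simulators the choice
of linear over log-linear interpolation is numerically immaterial.
AUC(0, inf) adds a terminal extrapolation C_last / lambda_z, with lambda_z
from a log-linear regression over the terminal 10% of the grid; it is used
for closed-form oracle comparisons, while tabular reports use AUC_last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NCAResult", "auc_last", "auc_inf", "terminal_slope", "average_tissue_auc"]


@dataclass(frozen=True)
class NCAResult:
    auc_last: float
    t_last: float
    auc_inf: float | None = None


def _validate(times, conc):
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.shape != conc.shape or times.ndim != 1:
        raise ValueError("times and concentrations must be 1-D and equal length")
    if times.size >= 2 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(conc < -1e-12):
        raise ValueError("negative concentrations")
    return times, np.clip(conc, 0.0, None)


def auc_last(times, concentrations) -> float:
    """Linear trapezoidal AUC over [t0, t_last]; a single point has zero area."""
    times, conc = _validate(times, concentrations)
    if times.size < 2:
        return 0.0
    return float(np.trapezoid(conc, times))


def terminal_slope(times, concentrations, fraction: float = 0.1) -> float:
    """Terminal elimination rate constant lambda_z (1/h) by log-linear
    regression on the last ``fraction`` of the grid (at least 3 points)."""
    times, conc = _validate(times, concentrations)
    n = max(3, int(np.ceil(fraction * times.size)))
    t, c = times[-n:], conc[-n:]
    pos = c > 0
    if pos.sum() < 3:
        raise ValueError("not enough positive terminal points for lambda_z")
    slope = np.polyfit(t[pos], np.log(c[pos]), 1)[0]
    lam = -slope
    if lam <= 0:
        raise ValueError("terminal phase is not declining; cannot extrapolate")
    return float(lam)


def auc_inf(times, concentrations, fraction: float = 0.1) -> float:
    """AUC(0, inf) = AUC_last + C_last / lambda_z."""
    times, conc = _validate(times, concentrations)
    lam = terminal_slope(times, conc, fraction)
    return auc_last(times, conc) + float(conc[-1]) / lam


def average_tissue_auc(result, tissues) -> float:
    """Unweighted mean of per-tissue AUC_last over the named compartments of
    a simulation result (the tissue-averaged exposure used for full-model
    report rows)."""
    tissues = list(tissues)
    missing = [t for t in tissues if t not in result.concentrations]
    if missing:
        raise KeyError(f"compartment(s) not in result: {missing}")
    values = [auc_last(result.times, result.concentrations[t]) for t in tissues]
    return float(np.mean(values))
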