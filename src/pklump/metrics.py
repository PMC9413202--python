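"""Model-compatibility metrics.

Two simulated or reported quantities are deemed compatible when their ratio
lies within the 2-fold range [0.5, 2], boundaries inclusive.  On top of the
per-pair verdicts this module provides study-level summaries: pass counts
per model pair and compartment scope, the accuracy-of-AUC statistic that
converts a lumped-model exposure into a theoretical compartment-model
exposure through the clearance ratio, the Vd/fu ratio and its power-law
relation between models, and the back-prediction of tissue concentrations
from a compartment-model profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "twofold_range",
    "within_twofold",
    "compatibility_counts",
    "auc_accuracy",
    "vd_over_fu",
    "fit_power_law",
    "back_predict_tissue_concentration",
    "format_with_twofold",
]

MODELS = ("pbpk", "lumped", "compartment")


def twofold_range(x: float) -> tuple[float, float]:
    """The acceptance interval (x/2, 2x) around a positive reference value."""
    if not x > 0:
        raise ValueError(f"2-fold range requires a positive value, got {x}")
    return (x / 2.0, 2.0 * x)


def within_twofold(a: float, b: float) -> bool:
    """True when a/b lies in [0.5, 2], boundaries inclusive (symmetric in a, b)."""
    if not (a > 0 and b > 0):
        raise ValueError("2-fold comparison requires positive values")
    r = a / b
    return 0.5 <= r <= 2.0


def _pair_verdict(row: pd.Series, cols: tuple[str, str]) -> bool | None:
    a, b = row[cols[0]], row[cols[1]]
    if pd.isna(a) or pd.isna(b):
        return None
    return within_twofold(float(a), float(b))


def compatibility_counts(
    report: pd.DataFrame,
    pair: tuple[str, str] = ("pbpk", "lumped"),
    scope: str = "central",
) -> tuple[int, int]:
    """Count compounds whose verdicts pass for a model pair and scope.

    ``report`` carries one row per compound with columns
    ``auc_central_<model>``, ``auc_peripheral_<model>`` and ``cl_<model>``
    (peripheral entries may be missing for one-compartment drugs, which are
    then excluded from peripheral totals).  Scopes:

    - ``central`` / ``peripheral``: the AUC of that compartment;
    - ``both``: central and peripheral jointly (a compound passes only if
      every comparable verdict is true);
    - ``cl``: clearance, compared across *all three* models as the maximum
      pairwise ratio when pair covers all models, else the named pair.
    """
    if report.empty:
        raise ValueError("empty compatibility report")
    for m in pair:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}")

    if scope == "cl":
        cols = [f"cl_{m}" for m in MODELS]
        n_pass = n_total = 0
        for _, row in report.iterrows():
            vals = [row[c] for c in cols if c in report.columns and pd.notna(row[c])]
            if len(vals) < 2:
                continue
            n_total += 1
            vals = np.asarray(vals, dtype=float)
            if max(vals) / min(vals) <= 2.0:
                n_pass += 1
        return n_pass, n_total

    if scope in ("central", "peripheral"):
        cols = (f"auc_{scope}_{pair[0]}", f"auc_{scope}_{pair[1]}")
        verdicts = report.apply(_pair_verdict, axis=1, cols=cols)
        done = verdicts.dropna()
        return int(done.sum()), int(done.size)

    if scope == "both":
        n_pass = n_total = 0
        for _, row in report.iterrows():
            vs = []
            for s in ("central", "peripheral"):
                v = _pair_verdict(row, (f"auc_{s}_{pair[0]}", f"auc_{s}_{pair[1]}"))
                if v is not None:
                    vs.append(v)
            if not vs:
                continue
            n_total += 1
            n_pass += all(vs)
        return n_pass, n_total

    raise ValueError(f"unknown scope {scope!r}")


def auc_accuracy(
    auc_lcen: float,
    cl_lumped: float,
    cl_compartment: float,
    auc_compartment_observed: float,
) -> float:
    """Accuracy of the AUC between lumped and compartment models.

    The theoretical compartment-model exposure is the lumped central
    exposure rescaled by the clearance ratio,
    ``AUC_theory = AUC_lcen * CL_lumped / CL_compartment``; the accuracy is
    the observed compartment AUC divided by this theoretical value.  Values
    near one indicate compatible models.  Invariant under a common
    rescaling of both AUCs.
    """
    if min(auc_lcen, cl_lumped, cl_compartment, auc_compartment_observed) <= 0:
        raise ValueError("accuracy-of-AUC inputs must be > 0")
    theoretical = auc_lcen * (cl_lumped / cl_compartment)
    return auc_compartment_observed / theoretical


def vd_over_fu(vc: float, vp: float | None, fu: float) -> float:
    """(Vc + Vp)/fu with Vp = 0 for one-compartment drugs; units follow the
    inputs (typically L/kg)."""
    if not (0.0 < fu <= 1.0):
        raise ValueError(f"fu must be in (0, 1], got {fu}")
    return (vc + (vp or 0.0)) / fu


def fit_power_law(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of log y on log x for the relation y = a*x**b.

    Returns (a, b, r_squared).  Requires at least 3 strictly positive pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    b, loga = np.polyfit(lx, ly, 1)
    pred = loga + b * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.exp(loga)), float(b), r2


def back_predict_tissue_concentration(
    c_p: float | np.ndarray,
    vp_compartment: float,
    vp_lumped: float,
    kp_t: float,
    k_lump: float,
) -> float | np.ndarray:
    """Reconstruct a full-model tissue concentration from a compartment-model
    peripheral concentration:
    ``C_T = C_p * (Vp_compartment / Vp_lumped) * (Kp_T / K_lump)``.
    """
    if min(vp_compartment, vp_lumped, kp_t, k_lump) <= 0:
        raise ValueError("back-prediction factors must be > 0")
    return c_p * (vp_compartment / vp_lumped) * (kp_t / k_lump)


def format_with_twofold(value: float, digits: int = 3) -> str:
    """Render ``value (low-high)`` as in the study's report tables."""
    lo, hi = twofold_range(value)
    fmt = f"{{:.{digits}f}}"
    return f"{fmt.format(value)} ({fmt.format(lo)}-{fmt.format(hi)})"
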