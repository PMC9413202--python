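"""Classical one- and two-compartment PK models.

Parameters are the usual clearance parameterisation: CL (L/h), central
volume Vc (L), and for the two-compartment model a peripheral volume Vp (L)
and inter-compartmental clearance Q (L/h); oral absorption is first order
with rate constant Ka (1/h).  Literature oral parameters are apparent
(CL/F, V/F); no bioavailability correction is applied.

The one-compartment oral model is evaluated in closed form.  The
two-compartment model is integrated through the same linear-ODE contract as
the whole-body model; a closed-form bi/tri-exponential solution is provided
for cross-checks and as the fast model function for least-squares fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .nca import auc_inf
from .pbpk import DEPOT, ELIMINATED, ODESystem, SimulationResult, simulate

__all__ = [
    "CompartmentParameters",
    "simulate_compartment",
    "build_compartment_odes",
    "one_compartment_oral_conc",
    "two_compartment_oral_conc",
    "auc_inf_analytic",
    "fit_compartment_model",
]

CENTRAL = "central"
PERIPHERAL = "peripheral"


@dataclass(frozen=True)
class CompartmentParameters:
    """Parameters of a 1- or 2-compartment model with first-order absorption."""

    cl: float
    vc: float
    ka: float
    dose: float
    n_compartments: int = 1
    vp: float | None = None
    q: float | None = None
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.cl <= 0 or self.vc <= 0:
            raise ValueError("CL and Vc must be > 0")
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.n_compartments == 2 and not (
            self.vp and self.vp > 0 and self.q and self.q > 0
        ):
            raise ValueError("two-compartment model requires Vp > 0 and Q > 0")
        if self.route == "oral" and self.dose > 0 and self.ka <= 0:
            raise ValueError("oral dosing requires Ka > 0")
        if self.route not in ("oral", "iv_bolus"):
            raise ValueError(f"unknown route {self.route!r}")

    @property
    def vd(self) -> float:
        """Apparent volume of distribution Vc + Vp (L)."""
        return self.vc + (self.vp or 0.0)


def one_compartment_oral_conc(
    t: np.ndarray, dose: float, cl: float, vc: float, ka: float
) -> np.ndarray:
    """Closed-form central concentration after a single oral dose:
    C(t) = D*Ka / (Vc*(Ka-ke)) * (exp(-ke t) - exp(-Ka t)), ke = CL/Vc."""
    t = np.asarray(t, dtype=float)
    ke = cl / vc
    if np.isclose(ka, ke, rtol=1e-12):
        # Removable singularity: limit Ka -> ke.
        return dose * ke * t * np.exp(-ke * t) / vc
    return dose * ka / (vc * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


def _two_compartment_exponents(cl: float, vc: float, vp: float, q: float):
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    root = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return k21, alpha, beta


def two_compartment_oral_conc(
    t: np.ndarray, dose: float, cl: float, vc: float, vp: float, q: float, ka: float
) -> np.ndarray:
    """Closed-form central concentration of the two-compartment oral model
    (tri-exponential; raises on coincident exponents)."""
    t = np.asarray(t, dtype=float)
    k21, alpha, beta = _two_compartment_exponents(cl, vc, vp, q)
    for lam in (alpha, beta):
        if np.isclose(ka, lam, rtol=1e-10):
            raise FloatingPointError("Ka coincides with a disposition exponent")
    coef = dose * ka / vc
    c = (
        (k21 - alpha) / ((ka - alpha) * (beta - alpha)) * np.exp(-alpha * t)
        + (k21 - beta) / ((ka - beta) * (alpha - beta)) * np.exp(-beta * t)
        + (k21 - ka) / ((alpha - ka) * (beta - ka)) * np.exp(-ka * t)
    )
    return coef * c


def build_compartment_odes(params: CompartmentParameters) -> ODESystem:
    """Linear amount-based system for either model (shared solver contract)."""
    names = [DEPOT, CENTRAL]
    if params.n_compartments == 2:
        names.append(PERIPHERAL)
    names.append(ELIMINATED)
    idx = {n: i for i, n in enumerate(names)}
    A = np.zeros((len(names), len(names)))
    A[idx[DEPOT], idx[DEPOT]] = -params.ka
    A[idx[CENTRAL], idx[DEPOT]] = params.ka
    ke = params.cl / params.vc
    A[idx[CENTRAL], idx[CENTRAL]] -= ke
    A[idx[ELIMINATED], idx[CENTRAL]] += ke
    if params.n_compartments == 2:
        k12 = params.q / params.vc
        k21 = params.q / params.vp
        A[idx[CENTRAL], idx[CENTRAL]] -= k12
        A[idx[PERIPHERAL], idx[CENTRAL]] += k12
        A[idx[PERIPHERAL], idx[PERIPHERAL]] -= k21
        A[idx[CENTRAL], idx[PERIPHERAL]] += k21
    volumes = {CENTRAL: params.vc}
    if params.n_compartments == 2:
        volumes[PERIPHERAL] = params.vp
    dose_state = DEPOT if params.route == "oral" else CENTRAL
    events = ((0.0, dose_state, params.dose),) if params.dose > 0 else ()
    return ODESystem(
        state_names=tuple(names),
        matrix=A,
        volumes=volumes,
        dose_events=events,
        meta={"model": f"{params.n_compartments}-compartment", "dose": params.dose},
    )


def simulate_compartment(
    params: CompartmentParameters, grid: np.ndarray, **solver_kwargs
) -> SimulationResult:
    """Simulate the compartment model on a grid starting at 0.

    The one-compartment oral model uses the closed form; everything else
    goes through the stiff ODE path (also used when Ka collides with the
    elimination exponent, where the closed form is singular).
    """
    grid = np.asarray(grid, dtype=float)
    if (
        params.n_compartments == 1
        and params.route == "oral"
        and not np.isclose(params.ka, params.cl / params.vc, rtol=1e-9)
    ):
        conc = one_compartment_oral_conc(
            grid, params.dose, params.cl, params.vc, params.ka
        )
        depot = params.dose * np.exp(-params.ka * grid)
        central = conc * params.vc
        return SimulationResult(
            times=grid,
            amounts={DEPOT: depot, CENTRAL: central},
            concentrations={CENTRAL: conc},
            eliminated=params.dose - depot - central,
            dose=params.dose,
        )
    return simulate(build_compartment_odes(params), grid, **solver_kwargs)


def auc_inf_analytic(params: CompartmentParameters) -> float:
    """AUC(0, inf) of the central compartment: F*Dose/CL with F = 1 (apparent
    oral parameterisation)."""
    return params.dose / params.cl


def fit_compartment_model(
    times: np.ndarray,
    conc: np.ndarray,
    dose: float,
    n_compartments: int = 2,
    route: str = "oral",
    loq_fraction: float = 1e-4,
) -> CompartmentParameters:
    """Least-squares fit of a compartment model to a concentration profile.

    Optimisation runs over log-parameters and log-concentration residuals
    (uniform relative weighting across the decades a PK profile spans),
    restricted to points above ``loq_fraction`` of the peak — the analogue
    of an assay quantification limit, which keeps the numerically tiny
    leading edge from dominating the cost.  Residuals carry quadrature
    weights so non-uniform grids do not bias the fit, and the
    absorption/distribution split of an oral profile admits local minima,
    so several heuristic starts are tried and the best kept.  Intended for
    dense, low-noise simulated profiles.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    cmax = float(np.max(conc))
    if cmax <= 0:
        raise ValueError("profile has no positive concentrations")
    mask = (times > 0) & (conc > loq_fraction * cmax)
    t, c = times[mask], conc[mask]
    auc = auc_inf(times, conc)
    cl0 = dose / auc
    t_max = t[np.argmax(c)]
    vc0 = dose / cmax
    ka0 = max(2.0 / t_max, 0.05)

    if n_compartments == 1:
        starts = [[cl0, vc0, ka0], [cl0, vc0, 10.0 * ka0]]

        def model(x):
            cl, vc, ka = np.exp(x)
            return one_compartment_oral_conc(t, dose, cl, vc, ka)

    else:
        # Starts differ in how total volume is split between central and
        # peripheral and in the absorption rate guess.
        starts = [
            [cl0, vc0, vc0, cl0, ka0],
            [cl0, vc0 / 20.0, vc0, 10.0 * cl0, ka0],
            [cl0, vc0 / 20.0, vc0, 10.0 * cl0, 10.0 * ka0],
            [cl0, vc0, vc0 / 20.0, cl0, ka0],
        ]

        def model(x):
            cl, vc, vp, q, ka = np.exp(x)
            try:
                return two_compartment_oral_conc(t, dose, cl, vc, vp, q, ka)
            except FloatingPointError:
                return np.full_like(t, np.inf)

    # Quadrature weights make the cost approximate the integrated squared
    # log-residual, so non-uniform grids do not bias the fit.
    quad = np.sqrt(np.gradient(t) / (t[-1] - t[0]))
    log_c = np.log(c)

    def residuals(x):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            pred = model(x)
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return np.full_like(t, 1e6)
        return quad * (np.log(pred) - log_c)

    best = None
    for start in starts:
        x0 = np.log(start)
        # Bounded log-space search keeps the exponents finite; wide enough
        # to be non-informative.
        sol = least_squares(
            residuals, x0, bounds=(x0 - np.log(1e6), x0 + np.log(1e6)),
            method="trf", max_nfev=600,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    p = np.exp(best.x)
    if n_compartments == 1:
        return CompartmentParameters(
            cl=p[0], vc=p[1], ka=p[2], dose=dose, n_compartments=1, route=route
        )
    return CompartmentParameters(
        cl=p[0],
        vc=p[1],
        vp=p[2],
        q=p[3],
        ka=p[4],
        dose=dose,
        n_compartments=2,
        route=route,
    )
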