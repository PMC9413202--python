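"""Whole-body perfusion-rate-limited PBPK model.

The state vector holds drug *amounts* (mg); concentrations are derived by
dividing by compartment volume only when results are assembled, which keeps
the integrator free of volume divisions.  All transfer is blood-flow
limited: the drug leaves a tissue at its emergent venous concentration
``C_T / (Kp_T / BP)``.

Topology
--------
venous blood -> lung -> arterial blood -> systemic tissues.  Gut and spleen
drain into the liver (portal vein) rather than into the venous pool; the
liver additionally receives a hepatic-arterial supply, so its total inflow
is ``Q_ha + Q_gut + Q_spleen``.  Liver and kidney eliminate drug at rates
``fu * CL_hep * C_li / (Kp_li / BP)`` and ``fu * CL_ki * C_ki / (Kp_ki / BP)``.
Oral doses enter a first-order depot emptying into the gut tissue, so
hepatic first-pass loss arises mechanistically.

Because every transfer is linear in the amounts, the whole system is a
constant-coefficient linear ODE ``dy/dt = A y``; the matrix is exposed on
the built system and doubles as the exact Jacobian for the stiff solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .physiology import (
    BLOOD_COMPARTMENTS,
    PERFUSED_TISSUES,
    DrugParameters,
    PhysiologySet,
    hepatic_clearance_well_stirred,  # noqa: F401  (re-exported: liver submodel)
)

__all__ = [
    "ODESystem",
    "SimulationResult",
    "SimulationError",
    "build_pbpk_odes",
    "simulate",
    "total_clearance",
    "effective_blood_clearance",
    "oral_bioavailability",
    "steady_state_blood_volume",
    "suggested_t_end",
    "default_grid",
    "graded_grid",
    "hybrid_grid",
]

DEPOT = "depot"
ELIMINATED = "eliminated"


class SimulationError(RuntimeError):
    """Integration failure, carrying the solver's diagnostic message."""


@dataclass(frozen=True)
class ODESystem:
    """A linear amount-based compartmental system ``dy/dt = matrix @ y``.

    ``state_names`` orders the state vector; ``volumes`` maps the
    drug-holding states to the volume used to convert amounts to
    concentrations (the depot and the elimination sink carry none).
    ``dose_events`` lists ``(time, state, amount)`` bolus inputs; only
    time 0 events are supported by :func:`simulate`.
    """

    state_names: tuple[str, ...]
    matrix: np.ndarray
    volumes: dict[str, float]
    dose_events: tuple[tuple[float, str, float], ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.state_names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match the state vector")

    @property
    def rhs(self):
        mat = self.matrix

        def f(t, y):
            return mat @ y

        return f

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(self.state_names))
        for t0, state, amount in self.dose_events:
            if t0 != 0.0:
                raise SimulationError("only time-0 dose events are supported")
            y0[self.index(state)] += amount
        return y0


@dataclass(frozen=True)
class SimulationResult:
    """Time grid plus per-compartment amount and concentration series."""

    times: np.ndarray
    amounts: dict[str, np.ndarray]
    concentrations: dict[str, np.ndarray]
    eliminated: np.ndarray
    dose: float

    def mass_balance_error(self) -> float:
        """Worst absolute deviation of (amounts + eliminated) from the dose,
        as a fraction of the dose (0 for a zero dose)."""
        if self.dose == 0.0:
            total = sum(a for a in self.amounts.values()) + self.eliminated
            return float(np.max(np.abs(total)))
        total = sum(a for a in self.amounts.values()) + self.eliminated
        return float(np.max(np.abs(total - self.dose)) / self.dose)

    def to_frame(self):
        """Tidy (time, compartment, concentration, amount) table."""
        import pandas as pd

        rows = []
        for name, amt in self.amounts.items():
            conc = self.concentrations.get(name)
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "compartment": name,
                        "concentration": np.nan if conc is None else conc,
                        "amount": amt,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _blood_return_coefficient(drug: DrugParameters, tissue: str, volume: float) -> float:
    """Rate coefficient (1/h per L/h of flow) of the emergent venous
    concentration: C_T/(Kp_T/BP) = amount * BP / (V_T * Kp_T)."""
    return drug.bp / (volume * drug.kp[tissue])


def build_pbpk_odes(phys: PhysiologySet, drug: DrugParameters) -> ODESystem:
    """Assemble the whole-body system for one drug.

    States: depot, the eleven perfused tissues, lung, arterial and venous
    blood, and a cumulative elimination sink.  With all clearances zero the
    matrix columns sum to zero, i.e. mass is conserved exactly.
    """
    missing = [t for t in PERFUSED_TISSUES + ("lung",) if t not in drug.kp]
    if missing:
        raise ValueError(f"drug lacks Kp for tissue(s): {missing}")

    names = (DEPOT,) + PERFUSED_TISSUES + ("lung",) + BLOOD_COMPARTMENTS + (ELIMINATED,)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    A = np.zeros((n, n))
    V = phys.volumes
    Q = phys.flows

    # Oral depot -> gut (first-order absorption).
    A[idx[DEPOT], idx[DEPOT]] = -drug.ka
    A[idx["gut"], idx[DEPOT]] = drug.ka

    c_art = 1.0 / V["arterial"]  # arterial concentration per unit amount
    q_li_total = phys.liver_total_flow

    for t in PERFUSED_TISSUES:
        r = _blood_return_coefficient(drug, t, V[t])
        if t == "liver":
            # Hepatic artery in; portal inflow handled with gut/spleen rows.
            A[idx[t], idx["arterial"]] += Q["liver"] * c_art
            A[idx["arterial"], idx["arterial"]] -= Q["liver"] * c_art
            outflow = q_li_total * r
            A[idx[t], idx[t]] -= outflow
            A[idx["venous"], idx[t]] += outflow
            elim = drug.fu * drug.cl_hep * r
            A[idx[t], idx[t]] -= elim
            A[idx[ELIMINATED], idx[t]] += elim
            continue
        # Arterial inflow.
        A[idx[t], idx["arterial"]] += Q[t] * c_art
        A[idx["arterial"], idx["arterial"]] -= Q[t] * c_art
        # Venous (or portal) outflow.
        A[idx[t], idx[t]] -= Q[t] * r
        drain = "liver" if t in ("gut", "spleen") else "venous"
        A[idx[drain], idx[t]] += Q[t] * r
        if t == "kidney":
            elim = drug.fu * drug.cl_ki * r
            A[idx[t], idx[t]] -= elim
            A[idx[ELIMINATED], idx[t]] += elim

    # Venous -> lung -> arterial.
    c_ven = 1.0 / V["venous"]
    r_lu = _blood_return_coefficient(drug, "lung", V["lung"])
    A[idx["lung"], idx["venous"]] += Q["lung"] * c_ven
    A[idx["venous"], idx["venous"]] -= Q["lung"] * c_ven
    A[idx["lung"], idx["lung"]] -= Q["lung"] * r_lu
    A[idx["arterial"], idx["lung"]] += Q["lung"] * r_lu

    volumes = {t: V[t] for t in PERFUSED_TISSUES + ("lung",) + BLOOD_COMPARTMENTS}
    dose_state = DEPOT if drug.route == "oral" else "venous"
    events = ((0.0, dose_state, drug.dose),) if drug.dose > 0 else ()
    return ODESystem(
        state_names=names,
        matrix=A,
        volumes=volumes,
        dose_events=events,
        meta={"drug": drug.name, "model": "pbpk", "dose": drug.dose},
    )


def simulate(
    system: ODESystem,
    grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> SimulationResult:
    """Integrate the system on a strictly increasing grid starting at 0.

    A stiff solver with the exact (constant) Jacobian is used by default:
    partition coefficients spanning orders of magnitude make the rate
    matrix badly scaled.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least two points")
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must start at 0 and be strictly increasing")

    y0 = system.initial_state()
    mat = system.matrix
    sol = solve_ivp(
        system.rhs,
        (grid[0], grid[-1]),
        y0,
        method=method,
        t_eval=grid,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: mat,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")

    amounts: dict[str, np.ndarray] = {}
    concentrations: dict[str, np.ndarray] = {}
    eliminated = np.zeros_like(grid)
    for i, name in enumerate(system.state_names):
        series = sol.y[i]
        if name == ELIMINATED:
            eliminated = series
            continue
        amounts[name] = series
        if name in system.volumes:
            concentrations[name] = series / system.volumes[name]
    dose = sum(a for _, _, a in system.dose_events)
    return SimulationResult(
        times=grid,
        amounts=amounts,
        concentrations=concentrations,
        eliminated=eliminated,
        dose=dose,
    )


def total_clearance(cl_hep: float, cl_ki: float, cl_others: float = 0.0) -> float:
    """Total clearance as the sum of organ clearances (only liver and kidney
    eliminate in this model, so ``cl_others`` defaults to 0)."""
    if cl_hep < 0 or cl_ki < 0 or cl_others < 0:
        raise ValueError("clearances must be >= 0")
    return cl_hep + cl_ki + cl_others


def effective_blood_clearance(phys: PhysiologySet, drug: DrugParameters) -> float:
    """Systemic blood clearance implied by the tissue-level elimination terms.

    At the integral (AUC) level the liver sees inflow at the arterial AUC,
    so its elimination is flow-attenuated; likewise the kidney:

    ``CL_b = fu*CL_hep*Q_li/(Q_li + fu*CL_hep) + fu*CL_ki*Q_ki/(Q_ki + fu*CL_ki)``

    For an IV bolus the venous AUC(0, inf) equals dose / CL_b exactly.
    """
    q_li = phys.liver_total_flow
    q_ki = phys.flows["kidney"]
    cl_h = drug.fu * drug.cl_hep
    cl_k = drug.fu * drug.cl_ki
    out = 0.0
    if cl_h > 0:
        out += cl_h * q_li / (q_li + cl_h)
    if cl_k > 0:
        out += cl_k * q_ki / (q_ki + cl_k)
    return out


def oral_bioavailability(phys: PhysiologySet, drug: DrugParameters) -> float:
    """Fraction of an oral dose escaping hepatic first-pass extraction,
    assuming complete absorption from the depot:
    ``F = Q_li / (Q_li + fu * CL_hep)``."""
    q_li = phys.liver_total_flow
    return q_li / (q_li + drug.fu * drug.cl_hep)


def steady_state_blood_volume(phys: PhysiologySet, drug: DrugParameters) -> float:
    """Blood-referenced steady-state distribution volume (L):
    ``V_ar + V_ve + sum_T V_T * Kp_T / BP`` over all tissues including lung."""
    v = phys.volumes["arterial"] + phys.volumes["venous"]
    for t in PERFUSED_TISSUES + ("lung",):
        v += phys.volumes[t] * drug.kp[t] / drug.bp
    return v


def suggested_t_end(
    phys: PhysiologySet,
    drug: DrugParameters,
    n_half_lives: float = 7.0,
    t_min: float = 24.0,
    t_max: float = 1e5,
) -> float:
    """Drug-specific simulation interval, n half-lives of the effective
    terminal phase (t_half = ln2 * Vss_blood / CL_blood), clipped to
    [t_min, t_max] hours.  Mirrors study designs that follow each drug over
    an interval matched to its persistence (e.g. 48 h vs 312 h)."""
    cl_b = effective_blood_clearance(phys, drug)
    if cl_b <= 0:
        return t_max
    t_half = np.log(2.0) * steady_state_blood_volume(phys, drug) / cl_b
    return float(np.clip(n_half_lives * t_half, t_min, t_max))


def default_grid(t_end: float = 48.0, n_points: int = 2001) -> np.ndarray:
    """Uniform simulation grid on [0, t_end] hours, dense enough that linear
    trapezoidal NCA is insensitive to the spacing."""
    if t_end <= 0 or n_points < 2:
        raise ValueError("t_end must be > 0 and n_points >= 2")
    return np.linspace(0.0, t_end, n_points)


def graded_grid(t_end: float, n_points: int = 3001, t_first: float = 1e-4) -> np.ndarray:
    """Geometrically spaced grid on [0, t_end] (first positive point at
    ``t_first``).  Resolves the fast blood-mixing transient after an IV
    bolus, which a uniform grid under-samples when the window spans many
    half-lives; needed for accurate trapezoidal AUC of bolus profiles."""
    if t_end <= t_first or n_points < 3:
        raise ValueError("need t_end > t_first and n_points >= 3")
    return np.concatenate([[0.0], np.geomspace(t_first, t_end, n_points - 1)])


def hybrid_grid(t_end: float, n_points: int = 1501, t_first: float = 1e-3) -> np.ndarray:
    """Union of a geometric and a uniform grid on [0, t_end]: resolves both
    the early absorption/mixing phase and the terminal phase on windows
    spanning many half-lives.  The default grid for drug-specific windows."""
    half = max(n_points // 2, 2)
    return np.union1d(graded_grid(t_end, half, t_first), default_grid(t_end, half))
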