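"""Synthetic drug panels and packaged result-table fixtures.

The study design calls for a panel of approved drugs chosen to span wide
ranges of clearance, distribution volume and protein binding.  The original
per-drug input parameterisations are not redistributable, so this module
generates *synthetic* drugs with physiologically plausible parameter
ranges.  Draws are log-uniform (PK parameters vary over orders of
magnitude) and fully reproducible from a seed.  Panel generation stratifies
the intrinsic-clearance axis so that, like the real selection, a panel
deliberately spans low- to high-extraction drugs.

The packaged CSV fixtures transcribe the study's printed per-compound
result tables (central AUC, peripheral AUC and clearance for the three
models); they exercise the comparison layer only and are never used to
parameterise simulations, so the two testing surfaces stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .physiology import (
    NET_TISSUES,
    PERFUSED_TISSUES,
    DrugParameters,
    PhysiologySet,
    hepatic_clearance_well_stirred,
)

__all__ = [
    "DrugProfile",
    "generate_drug",
    "generate_panel",
    "generate_matched_kinetics_drug",
    "perturb_drug",
    "fixture_tables",
    "DEFAULT_PROFILE",
]

_TISSUES_WITH_LUNG = PERFUSED_TISSUES + ("lung",)


@dataclass(frozen=True)
class DrugProfile:
    """Sampling ranges (low, high) for each drug parameter.

    Defaults cover the span seen across marketed small-molecule drugs:
    unbound fractions from heavily bound (1%) to unbound, blood:plasma
    ratios around unity, first-order absorption over 0.2-3 /h, intrinsic
    clearances from restrictive to flow-limited, modest renal clearance,
    and tissue partition coefficients across two orders of magnitude.
    """

    fu: tuple[float, float] = (0.01, 1.0)
    bp: tuple[float, float] = (0.55, 2.0)
    ka: tuple[float, float] = (0.2, 3.0)
    cl_int: tuple[float, float] = (1.0, 1.0e4)
    cl_ki: tuple[float, float] = (0.05, 10.0)
    kp: tuple[float, float] = (0.2, 20.0)
    dose: float = 100.0
    route: str = "oral"

    def __post_init__(self) -> None:
        for name in ("fu", "bp", "ka", "cl_int", "cl_ki", "kp"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name!r} must satisfy 0 < low <= high")


DEFAULT_PROFILE = DrugProfile()


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, u=None) -> float:
    if lo == hi:
        return lo
    u = rng.uniform() if u is None else u
    return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))


def generate_drug(
    profile: DrugProfile,
    seed: int | np.random.Generator,
    phys: PhysiologySet,
    name: str = "synthetic",
    _cl_int_quantile: float | None = None,
) -> DrugParameters:
    """Draw one drug from the profile (log-uniform in every range).

    Hepatic clearance is derived from the drawn intrinsic clearance through
    the well-stirred liver model using the physiology's total hepatic flow.
    Identical seeds give identical drugs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fu = _log_uniform(rng, *profile.fu)
    bp = _log_uniform(rng, *profile.bp)
    ka = _log_uniform(rng, *profile.ka)
    cl_int = _log_uniform(rng, *profile.cl_int, u=_cl_int_quantile)
    cl_ki = _log_uniform(rng, *profile.cl_ki)
    kp = {t: _log_uniform(rng, *profile.kp) for t in _TISSUES_WITH_LUNG}
    cl_hep = hepatic_clearance_well_stirred(phys.liver_total_flow, fu, cl_int)
    return DrugParameters(
        name=name,
        fu=fu,
        bp=bp,
        ka=ka,
        cl_hep=cl_hep,
        cl_ki=cl_ki,
        kp=kp,
        dose=profile.dose,
        route=profile.route,
        cl_int=cl_int,
    )


def generate_panel(
    profile: DrugProfile,
    n: int,
    seed: int,
    phys: PhysiologySet,
    stratify_extraction: bool = True,
) -> list[DrugParameters]:
    """Generate a reproducible panel of ``n`` drugs.

    With ``stratify_extraction`` the intrinsic-clearance axis is sampled by
    shuffled stratified quantiles, mirroring a study design that picks
    compounds across the whole clearance spectrum; the remaining parameters
    are free log-uniform draws.
    """
    rng = np.random.default_rng(seed)
    quantiles: list[float | None]
    if stratify_extraction and n > 1:
        edges = np.linspace(0.0, 1.0, n + 1)
        qs = rng.uniform(edges[:-1], edges[1:])
        rng.shuffle(qs)
        quantiles = list(qs)
    else:
        quantiles = [None] * n
    return [
        generate_drug(
            profile, rng, phys, name=f"syn{i:02d}", _cl_int_quantile=quantiles[i]
        )
        for i in range(n)
    ]


def generate_matched_kinetics_drug(
    phys: PhysiologySet,
    k: float,
    bp: float = 1.0,
    fu: float = 0.1,
    cl_hep: float = 30.0,
    cl_ki: float = 5.0,
    dose: float = 100.0,
    route: str = "oral",
    ka: float = 1.0,
) -> DrugParameters:
    """Construct a drug for which lumping the NET tissues is exact.

    Every non-eliminating tissue gets ``Kp_T = Q_T * BP / (V_T * k)`` so all
    NET members share the blood-equilibration rate ``k`` (1/h) and behave as
    one kinetic unit.  Retained tissues and the lung get Kp = 1 (the lung
    then equilibrates on the fast blood time scale, keeping the central
    merge tight).
    """
    if k <= 0:
        raise ValueError("equilibration rate k must be > 0")
    kp = {t: 1.0 for t in _TISSUES_WITH_LUNG}
    for t in NET_TISSUES:
        kp[t] = phys.flows[t] * bp / (phys.volumes[t] * k)
    return DrugParameters(
        name=f"matched-k{k:g}",
        fu=fu,
        bp=bp,
        ka=ka,
        cl_hep=cl_hep,
        cl_ki=cl_ki,
        kp=kp,
        dose=dose,
        route=route,
    )


def perturb_drug(
    drug: DrugParameters, cv: float, rng: np.random.Generator
) -> DrugParameters:
    """One Monte-Carlo replicate: multiply fu, Ka, clearances and every Kp
    by independent lognormal factors with coefficient of variation ``cv``
    (median-preserving); fu is capped at 1."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return drug
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))

    def f() -> float:
        return float(rng.lognormal(mean=0.0, sigma=sigma))

    return replace(
        drug,
        fu=min(drug.fu * f(), 1.0),
        ka=drug.ka * f(),
        cl_hep=drug.cl_hep * f(),
        cl_ki=drug.cl_ki * f(),
        kp={t: v * f() for t, v in drug.kp.items()},
        cl_int=None,
    )


def fixture_tables() -> dict[str, pd.DataFrame]:
    """The packaged per-compound result tables.

    Returns ``{"central_auc": ..., "peripheral_auc": ..., "clearance": ...}``
    with columns (compound, pbpk, lumped, compartment); AUCs in mg*h/L,
    clearances in L/h/kg.  Compartment peripheral entries are NaN for the
    eleven one-compartment drugs.
    """
    out = {}
    pkg = resources.files("pklump.data")
    for key, fname in (
        ("central_auc", "table1_central_auc.csv"),
        ("peripheral_auc", "table2_peripheral_auc.csv"),
        ("clearance", "table3_clearance.csv"),
    ):
        with pkg.joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh)
    return out


def fixture_report() -> pd.DataFrame:
    """The fixture tables merged into a one-row-per-compound report with the
    column layout expected by :func:`pklump.metrics.compatibility_counts`."""
    tables = fixture_tables()
    report = tables["central_auc"].rename(
        columns={m: f"auc_central_{m}" for m in ("pbpk", "lumped", "compartment")}
    )
    periph = tables["peripheral_auc"].rename(
        columns={m: f"auc_peripheral_{m}" for m in ("pbpk", "lumped", "compartment")}
    )
    cl = tables["clearance"].rename(
        columns={m: f"cl_{m}" for m in ("pbpk", "lumped", "compartment")}
    )
    report = report.merge(periph, on="compound").merge(cl, on="compound")
    return report
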