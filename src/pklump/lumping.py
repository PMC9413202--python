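"""Proper lumping of the whole-body model.

Tissues with similar kinetic behaviour are merged into aggregate
compartments while conserving volume, blood flow and Kp-weighted drug
capacity:

    V_lump = sum V_T,   Q_lump = sum Q_T,   K_lump = sum(V_T Kp_T) / V_lump

The default scheme merges arterial blood, venous blood and lung into a
lumped central compartment (LCEN) and the seven non-eliminating tissues
(adipose, bone, brain, heart, muscle, skin, rest-of-body) into a single
non-eliminating tissues compartment (NET).  Gut, spleen, liver and kidney
are retained un-lumped: liver and kidney because they eliminate drug, gut
and spleen because they feed the liver via the portal vein (and the gut
receives the oral dose).

Inside LCEN the blood compartments enter the K_lump sum with an effective
partition coefficient equal to BP, so the LCEN concentration is a *blood*
concentration and drives tissue uptake exactly as venous/arterial blood
does in the full model.  Lumping a set of tissues is exact when all its
members share the equilibration rate ``Q_T * BP / (V_T * Kp_T)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .pbpk import DEPOT, ELIMINATED, ODESystem
from .physiology import (
    ALL_COMPARTMENTS,
    BLOOD_COMPARTMENTS,
    NET_TISSUES,
    RETAINED_TISSUES,
    DrugParameters,
    PhysiologySet,
)

__all__ = [
    "LumpingScheme",
    "LumpedParameters",
    "LumpingError",
    "default_scheme",
    "load_scheme",
    "lump_parameters",
    "build_lumped_odes",
    "peripheral_volume",
    "central_blood_volume",
]

LCEN = "lcen"
NET = "net"


class LumpingError(ValueError):
    """Invalid lumping scheme or lumped-parameter request."""


@dataclass(frozen=True)
class LumpingScheme:
    """Partition of the full compartment set into lumps and retained tissues."""

    lumps: dict[str, frozenset[str]]
    retained: frozenset[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        groups = dict(self.lumps)
        groups["<retained>"] = self.retained
        for gname, members in groups.items():
            for t in members:
                if t in seen:
                    raise LumpingError(
                        f"tissue {t!r} assigned to both {seen[t]!r} and {gname!r}"
                    )
                seen[t] = gname
        missing = [t for t in ALL_COMPARTMENTS if t not in seen]
        unknown = [t for t in seen if t not in ALL_COMPARTMENTS]
        if missing or unknown:
            raise LumpingError(
                f"scheme is not a partition of the compartment set: "
                f"missing={missing}, unknown={unknown}"
            )

    @property
    def central(self) -> str:
        """Name of the lump containing the blood pool."""
        for name, members in self.lumps.items():
            if set(BLOOD_COMPARTMENTS) <= members:
                return name
        raise LumpingError("no lump contains both arterial and venous blood")


@dataclass(frozen=True)
class LumpedParameters:
    """Aggregate volume (L), flow (L/h) and partition coefficient per lump;
    retained tissues keep their original values (not stored here)."""

    volumes: dict[str, float]
    flows: dict[str, float]
    kps: dict[str, float]


def default_scheme() -> LumpingScheme:
    """LCEN = blood pool + lung; NET = the non-eliminating tissues;
    gut, spleen, liver and kidney retained."""
    return LumpingScheme(
        lumps={
            LCEN: frozenset(BLOOD_COMPARTMENTS) | {"lung"},
            NET: frozenset(NET_TISSUES),
        },
        retained=frozenset(RETAINED_TISSUES),
    )


def load_scheme(source) -> LumpingScheme:
    """Read a scheme document: mapping of lump name -> tissue list, plus an
    optional ``retained`` list (defaults to everything unassigned)."""
    if isinstance(source, dict):
        doc = dict(source)
    elif isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    retained = frozenset(doc.pop("retained", []))
    lumps = {str(k): frozenset(v) for k, v in doc.items()}
    if not retained:
        assigned = set().union(*lumps.values()) if lumps else set()
        retained = frozenset(t for t in ALL_COMPARTMENTS if t not in assigned)
    return LumpingScheme(lumps=lumps, retained=retained)


def _member_kp(drug: DrugParameters, tissue: str) -> float:
    # Blood compartments carry an effective Kp equal to BP so that the lump
    # concentration stays blood-referenced.
    if tissue in BLOOD_COMPARTMENTS:
        return drug.bp
    return drug.kp[tissue]


def lump_parameters(
    phys: PhysiologySet, drug: DrugParameters, scheme: LumpingScheme | None = None
) -> LumpedParameters:
    """Aggregate V, Q and Kp per lump (volume-weighted Kp mean).

    Blood compartments contribute no flow of their own; the flow of a lump
    containing the blood pool is the cardiac output.
    """
    scheme = scheme or default_scheme()
    volumes: dict[str, float] = {}
    flows: dict[str, float] = {}
    kps: dict[str, float] = {}
    for name, members in scheme.lumps.items():
        v = sum(phys.volumes[t] for t in members)
        if set(BLOOD_COMPARTMENTS) <= members:
            q = phys.cardiac_output
        else:
            q = sum(phys.flows[t] for t in members)
        vk = sum(phys.volumes[t] * _member_kp(drug, t) for t in members)
        volumes[name] = v
        flows[name] = q
        kps[name] = vk / v
    return LumpedParameters(volumes=volumes, flows=flows, kps=kps)


def build_lumped_odes(
    phys: PhysiologySet,
    drug: DrugParameters,
    lumped: LumpedParameters | None = None,
    scheme: LumpingScheme | None = None,
) -> ODESystem:
    """Assemble the reduced system: depot, gut, spleen, liver, kidney, NET,
    LCEN and the elimination sink.

    LCEN distributes blood at the cardiac output and collects the returns
    of NET, liver and kidney; gut and spleen drain into the liver exactly
    as in the full model, preserving oral first-pass.  The LCEN amount is
    converted to a blood concentration through its effective volume
    ``V_lcen * K_lcen / BP``.
    """
    scheme = scheme or default_scheme()
    if set(scheme.lumps) != {LCEN, NET} or scheme.retained != frozenset(
        RETAINED_TISSUES
    ):
        raise LumpingError(
            "the lumped ODE builder supports the default two-lump scheme "
            "(central blood lump + NET, retained gut/spleen/liver/kidney)"
        )
    central = scheme.central  # raises if no lump holds the blood pool
    lumped = lumped or lump_parameters(phys, drug, scheme)

    names = (DEPOT, "gut", "spleen", "liver", "kidney", NET, LCEN, ELIMINATED)
    idx = {n: i for i, n in enumerate(names)}
    A = np.zeros((len(names), len(names)))
    V, Q = phys.volumes, phys.flows

    # Effective volumes: concentration = amount / v_eff, blood-referenced
    # for LCEN, tissue-referenced otherwise.
    v_lcen_eff = lumped.volumes[central] * lumped.kps[central] / drug.bp
    c_lcen = 1.0 / v_lcen_eff

    def ret_coeff(v: float, kp: float) -> float:
        return drug.bp / (v * kp)

    A[idx[DEPOT], idx[DEPOT]] = -drug.ka
    A[idx["gut"], idx[DEPOT]] = drug.ka

    q_li_total = phys.liver_total_flow
    # Retained tissues, fed from LCEN.
    for t, q_in, drain in (
        ("gut", Q["gut"], "liver"),
        ("spleen", Q["spleen"], "liver"),
        ("liver", Q["liver"], LCEN),
        ("kidney", Q["kidney"], LCEN),
    ):
        A[idx[t], idx[LCEN]] += q_in * c_lcen
        A[idx[LCEN], idx[LCEN]] -= q_in * c_lcen
        r = ret_coeff(V[t], drug.kp[t])
        q_out = q_li_total if t == "liver" else q_in
        A[idx[t], idx[t]] -= q_out * r
        A[idx[drain], idx[t]] += q_out * r
    # Elimination.
    for t, cl in (("liver", drug.cl_hep), ("kidney", drug.cl_ki)):
        r = ret_coeff(V[t], drug.kp[t])
        elim = drug.fu * cl * r
        A[idx[t], idx[t]] -= elim
        A[idx[ELIMINATED], idx[t]] += elim
    # NET lump.
    q_net = lumped.flows[NET]
    r_net = ret_coeff(lumped.volumes[NET], lumped.kps[NET])
    A[idx[NET], idx[LCEN]] += q_net * c_lcen
    A[idx[LCEN], idx[LCEN]] -= q_net * c_lcen
    A[idx[NET], idx[NET]] -= q_net * r_net
    A[idx[LCEN], idx[NET]] += q_net * r_net

    volumes = {
        "gut": V["gut"],
        "spleen": V["spleen"],
        "liver": V["liver"],
        "kidney": V["kidney"],
        NET: lumped.volumes[NET],
        LCEN: v_lcen_eff,
    }
    dose_state = DEPOT if drug.route == "oral" else LCEN
    events = ((0.0, dose_state, drug.dose),) if drug.dose > 0 else ()
    return ODESystem(
        state_names=names,
        matrix=A,
        volumes=volumes,
        dose_events=events,
        meta={"drug": drug.name, "model": "lumped", "dose": drug.dose},
    )


def peripheral_volume(
    phys: PhysiologySet,
    drug: DrugParameters,
    scheme: LumpingScheme | None = None,
    model: str = "pbpk",
) -> float:
    """Peripheral volume of distribution in L/kg.

    ``model='pbpk'`` sums ``V_T * Kp_T`` over the peripheral (NET) tissues;
    ``model='lumped'`` uses the aggregate ``V_net * K_net``.  With K_net
    from the lumping rule the two coincide algebraically.
    """
    scheme = scheme or default_scheme()
    members = scheme.lumps.get(NET)
    if not members:
        raise LumpingError("scheme has no peripheral (NET) lump")
    bw = phys.body_weight
    if model == "pbpk":
        return sum(phys.volumes[t] * drug.kp[t] for t in members) / bw
    if model == "lumped":
        lumped = lump_parameters(phys, drug, scheme)
        return lumped.volumes[NET] * lumped.kps[NET] / bw
    raise ValueError(f"model must be 'pbpk' or 'lumped', got {model!r}")


def central_blood_volume(phys: PhysiologySet, drug: DrugParameters) -> float:
    """Central volume (L/kg) of the blood-like pool: arterial + venous blood
    plus the lung scaled to blood reference, (V_ar + V_ve + V_lu*Kp_lu/BP)/BW."""
    v = (
        phys.volumes["arterial"]
        + phys.volumes["venous"]
        + phys.volumes["lung"] * drug.kp["lung"] / drug.bp
    )
    return v / phys.body_weight
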