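"""Physiological and drug-specific parameter sets.

Units are fixed package-wide: volumes in L, flows in L/h, amounts in mg,
concentrations in mg/L, clearances in L/h, time in h.  Per-kilogram
quantities (L/kg, L/h/kg) appear only in reports, where they are divided by
body weight.

The anatomical scaffold is a whole-body, perfusion-rate-limited model:
eleven systemically perfused tissues (adipose, bone, brain, gut, heart,
kidney, liver, muscle, skin, spleen, rest-of-body), the lung in series with
the blood pool, and separate arterial and venous blood compartments.  The
liver receives hepatic-arterial blood plus the portal venous outflow of gut
and spleen.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources

import yaml

__all__ = [
    "PERFUSED_TISSUES",
    "NET_TISSUES",
    "RETAINED_TISSUES",
    "BLOOD_COMPARTMENTS",
    "ALL_COMPARTMENTS",
    "PhysiologySet",
    "DrugParameters",
    "PhysiologyError",
    "DrugParameterError",
    "load_physiology",
    "derive_rest_of_body",
    "load_drug",
    "hepatic_clearance_well_stirred",
    "default_physiology",
    "with_dose",
]

#: Tissues perfused directly from the systemic (arterial) circulation.
#: The liver entry is its hepatic-arterial supply; portal flow is implied.
PERFUSED_TISSUES = (
    "adipose",
    "bone",
    "brain",
    "gut",
    "heart",
    "kidney",
    "liver",
    "muscle",
    "skin",
    "spleen",
    "rest_of_body",
)

#: Non-eliminating tissues, i.e. the members of the NET lump.
NET_TISSUES = ("adipose", "bone", "brain", "heart", "muscle", "skin", "rest_of_body")

#: Tissues kept un-lumped in the reduced model (eliminating organs plus the
#: splanchnic inflow tract that feeds the liver).
RETAINED_TISSUES = ("gut", "spleen", "liver", "kidney")

BLOOD_COMPARTMENTS = ("arterial", "venous")

#: Every drug-holding compartment of the full model (no depot).
ALL_COMPARTMENTS = PERFUSED_TISSUES + ("lung",) + BLOOD_COMPARTMENTS

_FLOW_TISSUES = PERFUSED_TISSUES + ("lung",)


class PhysiologyError(ValueError):
    """Invalid or inconsistent physiological parameter set."""


class DrugParameterError(ValueError):
    """Invalid drug-specific parameter set."""


@dataclass(frozen=True)
class PhysiologySet:
    """Tissue volumes, blood flows and body weight for one individual.

    Parameters
    ----------
    volumes
        Volume in L for every compartment in :data:`ALL_COMPARTMENTS`.
    flows
        Blood flow in L/h for every perfused tissue plus ``lung``; the lung
        flow equals the cardiac output.  The ``liver`` entry is the
        hepatic-arterial flow only.
    body_weight
        Body weight in kg.
    """

    volumes: dict[str, float]
    flows: dict[str, float]
    body_weight: float

    def __post_init__(self) -> None:
        missing_v = [t for t in ALL_COMPARTMENTS if t not in self.volumes]
        if missing_v:
            raise PhysiologyError(f"missing volume for tissue(s): {missing_v}")
        missing_q = [t for t in _FLOW_TISSUES if t not in self.flows]
        if missing_q:
            raise PhysiologyError(f"missing blood flow for tissue(s): {missing_q}")
        for t, v in self.volumes.items():
            if not v > 0:
                raise PhysiologyError(f"volume of {t!r} must be > 0, got {v}")
        for t, q in self.flows.items():
            if q < 0:
                raise PhysiologyError(f"flow of {t!r} must be >= 0, got {q}")
        if self.body_weight <= 0:
            raise PhysiologyError("body weight must be > 0")
        qsum = sum(self.flows[t] for t in PERFUSED_TISSUES)
        if abs(qsum - self.cardiac_output) > 1e-9 * max(self.cardiac_output, 1.0):
            raise PhysiologyError(
                "systemic tissue flows must sum to the cardiac output "
                f"(lung flow): sum={qsum!r}, cardiac output={self.cardiac_output!r}"
            )

    @property
    def cardiac_output(self) -> float:
        """Cardiac output in L/h (equal to the lung blood flow)."""
        return self.flows["lung"]

    @property
    def liver_total_flow(self) -> float:
        """Total hepatic inflow: hepatic artery plus gut and spleen outflow."""
        return self.flows["liver"] + self.flows["gut"] + self.flows["spleen"]

    def to_yaml(self) -> str:
        doc = {
            "body_weight": float(self.body_weight),
            "volumes": {t: float(v) for t, v in self.volumes.items()},
            "flows": {t: float(q) for t, q in self.flows.items()},
        }
        return yaml.safe_dump(doc, sort_keys=True)


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific inputs of the whole-body model.

    ``kp`` maps every non-blood tissue (including lung and liver) to its
    tissue:plasma partition coefficient.  ``cl_hep`` is either supplied
    directly or derived from an intrinsic clearance through the well-stirred
    liver model.
    """

    name: str
    fu: float
    bp: float
    ka: float
    cl_hep: float
    cl_ki: float
    kp: dict[str, float]
    dose: float
    route: str = "oral"
    cl_int: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fu <= 1.0):
            raise DrugParameterError(f"fu must be in (0, 1], got {self.fu}")
        if self.bp <= 0:
            raise DrugParameterError(f"blood:plasma ratio must be > 0, got {self.bp}")
        if self.ka < 0:
            raise DrugParameterError(f"Ka must be >= 0, got {self.ka}")
        if self.cl_hep < 0 or self.cl_ki < 0:
            raise DrugParameterError("clearances must be >= 0")
        if self.dose < 0:
            raise DrugParameterError("dose must be >= 0")
        if self.route not in ("oral", "iv_bolus"):
            raise DrugParameterError(f"unknown route {self.route!r}")
        missing = [t for t in PERFUSED_TISSUES + ("lung",) if t not in self.kp]
        if missing:
            raise DrugParameterError(f"missing Kp for tissue(s): {missing}")
        for t, k in self.kp.items():
            if not k > 0:
                raise DrugParameterError(f"Kp of {t!r} must be > 0, got {k}")

    @property
    def cl_total(self) -> float:
        """Total body clearance, hepatic plus renal (L/h)."""
        return self.cl_hep + self.cl_ki

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "fu": float(self.fu),
            "bp": float(self.bp),
            "ka": float(self.ka),
            "cl_hep": float(self.cl_hep),
            "cl_ki": float(self.cl_ki),
            "kp": {t: float(k) for t, k in self.kp.items()},
            "dose": float(self.dose),
            "route": self.route,
        }
        if self.cl_int is not None:
            doc["cl_int"] = float(self.cl_int)
        return yaml.safe_dump(doc, sort_keys=True)


def hepatic_clearance_well_stirred(q_li: float, fu: float, cl_int: float) -> float:
    """Well-stirred liver model: CL_hep = Q_li * fu * CL_int / (fu * CL_int + Q_li).

    The result is bounded by the hepatic blood flow ``q_li`` for any finite
    intrinsic clearance, and approaches ``fu * cl_int`` in the
    restrictively-cleared (low extraction) limit.
    """
    if q_li < 0 or fu < 0 or cl_int < 0:
        raise DrugParameterError("well-stirred model inputs must be >= 0")
    denom = fu * cl_int + q_li
    if denom == 0.0:
        return 0.0
    return q_li * fu * cl_int / denom


def _read_doc(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    if isinstance(source, (str, bytes)) and "\n" not in str(source):
        with open(source) as fh:
            return yaml.safe_load(fh)
    if isinstance(source, io.IOBase):
        return yaml.safe_load(source)
    return yaml.safe_load(source)


def derive_rest_of_body(
    volumes: dict[str, float],
    flows: dict[str, float],
    cardiac_output: float,
    total_body_volume: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Close the body over a rest-of-body compartment.

    The rest-of-body flow absorbs the difference between the cardiac output
    and the sum of the specified systemic flows; its volume absorbs the
    difference between the total body volume and the sum of specified
    volumes.  After closure the flow-sum identity holds exactly.
    """
    specified = [t for t in PERFUSED_TISSUES if t != "rest_of_body"]
    q_rest = cardiac_output - sum(flows[t] for t in specified)
    v_rest = total_body_volume - sum(
        volumes[t] for t in volumes if t != "rest_of_body"
    )
    if q_rest < 0:
        raise PhysiologyError(
            f"tissue flows exceed cardiac output by {-q_rest} L/h"
        )
    if v_rest <= 0:
        raise PhysiologyError(
            "specified volumes leave no positive rest-of-body volume "
            f"(remainder {v_rest} L)"
        )
    volumes = dict(volumes)
    flows = dict(flows)
    volumes["rest_of_body"] = v_rest
    flows["rest_of_body"] = q_rest
    return volumes, flows


def load_physiology(source) -> PhysiologySet:
    """Load a physiology document (YAML mapping, path, stream or dict).

    Required keys: ``body_weight``, ``volumes`` and ``flows``.  If the
    rest-of-body entries are absent they are derived by closure against
    ``cardiac_output`` (default: lung flow) and ``total_body_volume``
    (default: body weight at unit density).
    """
    doc = _read_doc(source)
    try:
        volumes = {str(k): float(v) for k, v in doc["volumes"].items()}
        flows = {str(k): float(v) for k, v in doc["flows"].items()}
        bw = float(doc["body_weight"])
    except (KeyError, TypeError) as exc:
        raise PhysiologyError(f"physiology document missing section: {exc}") from exc

    required = [t for t in ALL_COMPARTMENTS if t != "rest_of_body"]
    missing = [t for t in required if t not in volumes]
    if missing:
        raise PhysiologyError(f"missing volume for tissue(s): {missing}")

    if "rest_of_body" not in volumes or "rest_of_body" not in flows:
        co = float(doc.get("cardiac_output", flows.get("lung", 0.0)))
        tbv = float(doc.get("total_body_volume", bw))
        volumes, flows = derive_rest_of_body(volumes, flows, co, tbv)
    flows.setdefault("lung", sum(flows[t] for t in PERFUSED_TISSUES))
    return PhysiologySet(volumes=volumes, flows=flows, body_weight=bw)


def load_drug(
    source,
    phys: PhysiologySet | None = None,
    default_kp: float | None = None,
) -> DrugParameters:
    """Load a drug parameter document (YAML mapping, path, stream or dict).

    Either ``cl_hep`` or ``cl_int`` must be present; with only ``cl_int``
    the hepatic clearance is derived by the well-stirred model, which
    requires ``phys`` for the total hepatic blood flow.  ``default_kp``,
    if given, fills partition coefficients for tissues absent from the
    ``kp`` mapping.
    """
    doc = _read_doc(source)
    kp = {str(k): float(v) for k, v in dict(doc.get("kp", {})).items()}
    if default_kp is not None:
        for t in PERFUSED_TISSUES + ("lung",):
            kp.setdefault(t, float(default_kp))

    cl_int = doc.get("cl_int")
    if "cl_hep" in doc:
        cl_hep = float(doc["cl_hep"])
    elif cl_int is not None:
        if phys is None:
            raise DrugParameterError(
                "cl_int given without cl_hep: physiology needed for the "
                "well-stirred liver flow"
            )
        cl_hep = hepatic_clearance_well_stirred(
            phys.liver_total_flow, float(doc["fu"]), float(cl_int)
        )
    else:
        raise DrugParameterError("either cl_hep or cl_int must be provided")

    return DrugParameters(
        name=str(doc.get("name", "unnamed")),
        fu=float(doc["fu"]),
        bp=float(doc["bp"]),
        ka=float(doc.get("ka", 0.0)),
        cl_hep=cl_hep,
        cl_ki=float(doc.get("cl_ki", 0.0)),
        kp=kp,
        dose=float(doc.get("dose", 0.0)),
        route=str(doc.get("route", "oral")),
        cl_int=None if cl_int is None else float(cl_int),
    )


def default_physiology() -> PhysiologySet:
    """The bundled 70-kg reference adult, with rest-of-body closure applied."""
    with resources.files("pklump.data").joinpath("human_adult.yaml").open() as fh:
        return load_physiology(fh)


def with_dose(drug: DrugParameters, dose: float, route: str | None = None) -> DrugParameters:
    """Return a copy of ``drug`` with a different dose (and optionally route)."""
    return replace(drug, dose=dose, route=route or drug.route)
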