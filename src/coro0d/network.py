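"""The simulated system: aorta + coronary tree, stenoses, and outlet models.

The network is a rooted tree of cylindrical vessel segments. Each leaf carries
an outlet boundary model: a three-element Windkessel (proximal resistance Rp,
compliance C, distal resistance Rd) for the systemic circulation, or a
coronary outlet with arterial resistance Ra and compliance Ca, microvascular
resistance Ra_micro, intramyocardial compliance Cim referenced to the
intramyocardial pressure Pim(t), and venous microvascular resistance Rv_micro
draining to a fixed venous pressure. Venous microcirculation compliance is
deliberately omitted.

Units are mmHg, mL/s, cm, s throughout the public surface; blood is Newtonian
(mu = 0.04 poise, rho = 1.06 g/cm^3) in rigid vessels.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .waveforms import (
    PatientRecord,
    Waveform,
    scale_pim_waveform,
    ventricular_pressure_template,
)

__all__ = [
    "MMHG_DYN",
    "BLOOD_VISCOSITY",
    "BLOOD_DENSITY",
    "VesselSegment",
    "Stenosis",
    "WindkesselOutlet",
    "CoronaryOutlet",
    "VascularNetwork",
    "NetworkError",
    "poiseuille_resistance",
    "segment_resistance",
    "initialize_coronary_outlets",
    "initialize_systemic_outlet",
    "artery_rest_flow",
    "territory_mass_fraction",
]

#: dyn/cm^2 per mmHg
MMHG_DYN = 1333.22
#: blood dynamic viscosity, poise (g/(cm*s))
BLOOD_VISCOSITY = 0.04
#: blood density, g/cm^3
BLOOD_DENSITY = 1.06

#: default split of a coronary outlet's total resistance into
#: (Ra, Ra_micro, Rv_micro)
DEFAULT_RESISTANCE_SPLITS = (0.32, 0.52, 0.16)
#: default rest myocardial perfusion, mL/min per gram of myocardium
DEFAULT_REST_FLOW_PER_GRAM = 0.8
#: default intramyocardial-pressure territory factors (fraction of systolic
#: LV pressure transmitted to the territory); right ventricle compresses less
DEFAULT_TERRITORY_FACTORS = {"RCA": 0.5}
DEFAULT_TERRITORY_FACTOR = 1.0


class NetworkError(ValueError):
    """Invalid network topology or parameters."""


def poiseuille_resistance(length: float, radius: float,
                          viscosity: float = BLOOD_VISCOSITY) -> float:
    """Poiseuille resistance 8*mu*L/(pi*r^4) in mmHg*s/mL (inputs in cm, poise)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if length < 0:
        raise ValueError("length must be non-negative")
    return 8.0 * viscosity * length / (math.pi * radius**4) / MMHG_DYN


@dataclass
class VesselSegment:
    """A straight cylindrical vessel between two nodes (lengths/radii in cm)."""

    id: str
    proximal_node: str
    distal_node: str
    length: float
    radius: float

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise NetworkError(f"segment {self.id}: length and radius must be positive")

    @property
    def area(self) -> float:
        """Lumen cross-section, cm^2."""
        return math.pi * self.radius**2

    @property
    def viscous_resistance(self) -> float:
        """Poiseuille resistance at default blood viscosity, mmHg*s/mL."""
        return poiseuille_resistance(self.length, self.radius)

    @property
    def inertance(self) -> float:
        """Blood inertance rho*L/A, mmHg*s^2/mL."""
        return BLOOD_DENSITY * self.length / self.area / MMHG_DYN


def segment_resistance(segment: VesselSegment,
                       viscosity: float = BLOOD_VISCOSITY) -> float:
    """Poiseuille resistance of a segment at the given viscosity, mmHg*s/mL."""
    return poiseuille_resistance(segment.length, segment.radius, viscosity)


@dataclass
class Stenosis:
    """A focal lumen narrowing within a vessel segment (cm units)."""

    segment_id: str
    reference_radius: float
    minimal_lumen_radius: float
    lesion_length: float

    def __post_init__(self):
        if not 0 < self.minimal_lumen_radius < self.reference_radius:
            raise NetworkError(
                "stenosis requires 0 < minimal_lumen_radius < reference_radius"
            )
        if self.lesion_length <= 0:
            raise NetworkError("lesion_length must be positive")

    @property
    def percent_stenosis(self) -> float:
        """Diameter stenosis in % = 100*(1 - minimal/reference)."""
        return 100.0 * (1.0 - self.minimal_lumen_radius / self.reference_radius)

    @property
    def reference_area(self) -> float:
        return math.pi * self.reference_radius**2

    @property
    def minimal_lumen_area(self) -> float:
        return math.pi * self.minimal_lumen_radius**2


@dataclass
class WindkesselOutlet:
    """Three-element Windkessel: Rp in series with (C parallel Rd) to Pref."""

    Rp: float  # mmHg*s/mL
    C: float  # mL/mmHg
    Rd: float  # mmHg*s/mL
    reference_pressure: float = 0.0  # mmHg

    def __post_init__(self):
        if self.Rp <= 0 or self.Rd <= 0 or self.C <= 0:
            raise NetworkError("Windkessel Rp, Rd, C must be positive")


@dataclass
class CoronaryOutlet:
    """Coronary outlet: Ra + Ca, Ra_micro, Cim referenced to Pim(t), Rv_micro.

    Pim compresses the intramyocardial compartment during systole, producing
    the diastolic-dominant coronary flow pattern. venous microcirculation
    compliance is omitted.
    """

    Ra: float
    Ca: float
    Ra_micro: float
    Cim: float
    Rv_micro: float
    Pim: Waveform
    venous_pressure: float = 5.0
    artery: str = ""

    def __post_init__(self):
        if min(self.Ra, self.Ra_micro, self.Rv_micro) <= 0:
            raise NetworkError("coronary outlet resistances must be positive")
        if self.Ca <= 0 or self.Cim <= 0:
            raise NetworkError("coronary outlet compliances must be positive")

    @property
    def total_resistance(self) -> float:
        return self.Ra + self.Ra_micro + self.Rv_micro


Outlet = Union[WindkesselOutlet, CoronaryOutlet]


@dataclass
class VascularNetwork:
    """A rooted tree of segments with stenoses and one outlet per leaf."""

    segments: List[VesselSegment]
    stenoses: List[Stenosis] = field(default_factory=list)
    outlets: Dict[str, Outlet] = field(default_factory=dict)
    inflow_node: str = "inlet"

    # -- topology helpers ---------------------------------------------------

    def segment_by_id(self, segment_id: str) -> VesselSegment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise NetworkError(f"unknown segment id {segment_id!r}")

    def stenosis_on(self, segment_id: str) -> Optional[Stenosis]:
        for st in self.stenoses:
            if st.segment_id == segment_id:
                return st
        return None

    def children(self) -> Dict[str, List[VesselSegment]]:
        out: Dict[str, List[VesselSegment]] = {}
        for s in self.segments:
            out.setdefault(s.proximal_node, []).append(s)
        return out

    def nodes(self) -> List[str]:
        seen = {self.inflow_node}
        order = [self.inflow_node]
        for s in self.segments:
            for n in (s.proximal_node, s.distal_node):
                if n not in seen:
                    seen.add(n)
                    order.append(n)
        return order

    def leaf_nodes(self) -> List[str]:
        has_child = {s.proximal_node for s in self.segments}
        return [s.distal_node for s in self.segments if s.distal_node not in has_child]

    def leaf_segment(self, leaf_node: str) -> VesselSegment:
        for s in self.segments:
            if s.distal_node == leaf_node:
                return s
        raise NetworkError(f"no segment ends at node {leaf_node!r}")

    def path_segments(self, node: str) -> List[VesselSegment]:
        """Segments from the inflow node down to `node` (inclusive)."""
        parent = {s.distal_node: s for s in self.segments}
        path: List[VesselSegment] = []
        cur = node
        while cur != self.inflow_node:
            if cur not in parent:
                raise NetworkError(f"node {node!r} is not reachable from the root")
            seg = parent[cur]
            path.append(seg)
            cur = seg.proximal_node
        return list(reversed(path))

    def coronary_arteries(self) -> List[str]:
        names = []
        for o in self.outlets.values():
            if isinstance(o, CoronaryOutlet) and o.artery not in names:
                names.append(o.artery)
        return names

    def validate(self) -> None:
        """Reject cycles, multiple parents, orphan stenoses, and bare leaves."""
        if not self.segments:
            raise NetworkError("network has no segments")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate segment ids")
        parents: Dict[str, str] = {}
        for s in self.segments:
            if s.distal_node in parents:
                raise NetworkError(
                    f"node {s.distal_node!r} has multiple parents (not a tree)"
                )
            parents[s.distal_node] = s.id
        if self.inflow_node in parents:
            raise NetworkError("inflow node cannot have a parent")
        # connectivity / acyclicity via DFS from the root
        children = self.children()
        seen = set()
        stack = [self.inflow_node]
        while stack:
            node = stack.pop()
            if node in seen:
                raise NetworkError("network graph contains a cycle")
            seen.add(node)
            stack.extend(s.distal_node for s in children.get(node, []))
        unreached = {s.distal_node for s in self.segments} - seen
        if unreached:
            raise NetworkError(f"nodes not reachable from the root: {sorted(unreached)}")
        for leaf in self.leaf_nodes():
            if leaf not in self.outlets:
                raise NetworkError(f"leaf node {leaf!r} has no outlet model")
        for node in self.outlets:
            if node not in {s.distal_node for s in self.segments}:
                raise NetworkError(f"outlet attached to unknown node {node!r}")
            if node not in self.leaf_nodes():
                raise NetworkError(f"outlet attached to non-leaf node {node!r}")
        for st in self.stenoses:
            self.segment_by_id(st.segment_id)  # raises if orphan

    def copy(self) -> "VascularNetwork":
        # Waveforms are immutable in practice; share them across copies.
        new_outlets = {}
        for node, o in self.outlets.items():
            new_outlets[node] = dataclasses_replace_shallow(o)
        return VascularNetwork(
            segments=[copy.copy(s) for s in self.segments],
            stenoses=[copy.copy(st) for st in self.stenoses],
            outlets=new_outlets,
            inflow_node=self.inflow_node,
        )

    # -- JSON I/O -----------------------------------------------------------

    def to_json_dict(self) -> dict:
        outlets = []
        for node, o in self.outlets.items():
            if isinstance(o, WindkesselOutlet):
                outlets.append(
                    {
                        "node": node,
                        "kind": "windkessel",
                        "Rp": o.Rp,
                        "C": o.C,
                        "Rd": o.Rd,
                        "reference_pressure": o.reference_pressure,
                    }
                )
            else:
                outlets.append(
                    {
                        "node": node,
                        "kind": "coronary",
                        "artery": o.artery,
                        "Ra": o.Ra,
                        "Ca": o.Ca,
                        "Ra_micro": o.Ra_micro,
                        "Cim": o.Cim,
                        "Rv_micro": o.Rv_micro,
                        "venous_pressure": o.venous_pressure,
                    }
                )
        return {
            "inflow_node": self.inflow_node,
            "segments": [
                {
                    "id": s.id,
                    "from": s.proximal_node,
                    "to": s.distal_node,
                    "length_cm": s.length,
                    "radius_cm": s.radius,
                }
                for s in self.segments
            ],
            "stenoses": [
                {
                    "segment_id": st.segment_id,
                    "reference_radius_cm": st.reference_radius,
                    "minimal_lumen_radius_cm": st.minimal_lumen_radius,
                    "lesion_length_cm": st.lesion_length,
                }
                for st in self.stenoses
            ],
            "outlets": outlets,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    @classmethod
    def from_json_dict(cls, d: dict, pim: Optional[Waveform] = None) -> "VascularNetwork":
        segments = [
            VesselSegment(
                id=s["id"],
                proximal_node=s["from"],
                distal_node=s["to"],
                length=s["length_cm"],
                radius=s["radius_cm"],
            )
            for s in d["segments"]
        ]
        seg_by_id = {s.id: s for s in segments}
        stenoses = [
            Stenosis(
                segment_id=st["segment_id"],
                reference_radius=st.get(
                    "reference_radius_cm", seg_by_id[st["segment_id"]].radius
                ),
                minimal_lumen_radius=st["minimal_lumen_radius_cm"],
                lesion_length=st["lesion_length_cm"],
            )
            for st in d["stenoses"]
        ]
        outlets: Dict[str, Outlet] = {}
        for o in d.get("outlets", []):
            if o["kind"] == "windkessel":
                outlets[o["node"]] = WindkesselOutlet(
                    Rp=o.get("Rp", 1.0),
                    C=o.get("C", 1.0),
                    Rd=o.get("Rd", 1.0),
                    reference_pressure=o.get("reference_pressure", 0.0),
                )
            elif o["kind"] == "coronary":
                if pim is None:
                    # placeholder flat Pim; initialize_coronary_outlets replaces it
                    pim_wf = Waveform(np.linspace(0, 1, 17), np.zeros(17), 1.0)
                else:
                    pim_wf = pim
                outlets[o["node"]] = CoronaryOutlet(
                    Ra=o.get("Ra", 1.0),
                    Ca=o.get("Ca", 5e-4),
                    Ra_micro=o.get("Ra_micro", 1.0),
                    Cim=o.get("Cim", 5e-3),
                    Rv_micro=o.get("Rv_micro", 1.0),
                    Pim=pim_wf,
                    venous_pressure=o.get("venous_pressure", 5.0),
                    artery=o.get("artery", ""),
                )
            else:
                raise NetworkError(f"unknown outlet kind {o['kind']!r}")
        net = cls(
            segments=segments,
            stenoses=stenoses,
            outlets=outlets,
            inflow_node=d["inflow_node"],
        )
        net.validate()
        return net

    @classmethod
    def from_json(cls, path) -> "VascularNetwork":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def dataclasses_replace_shallow(o: Outlet) -> Outlet:
    """Shallow copy of an outlet dataclass (waveforms shared)."""
    return copy.copy(o)


# ---------------------------------------------------------------------------
# Parameter initialization from patient targets
# ---------------------------------------------------------------------------


def territory_mass_fraction(artery: str, fractions: Dict[str, float]) -> float:
    """Myocardial mass fraction perfused through a given artery.

    The left main supplies both the LAD and LCx territories, so an LM lesion's
    flow is the sum of the LM, LAD and LCx fractions.
    """
    if artery == "LM":
        return sum(fractions.get(a, 0.0) for a in ("LM", "LAD", "LCx"))
    if artery not in fractions:
        raise NetworkError(f"no myocardial mass fraction for artery {artery!r}")
    return fractions[artery]


def artery_rest_flow(patient: PatientRecord, artery: str,
                     rest_flow_per_gram: float = DEFAULT_REST_FLOW_PER_GRAM) -> float:
    """Resting flow allocated to an artery, mL/s.

    rest_flow_per_gram is in mL/min per gram of myocardium.
    """
    frac = territory_mass_fraction(artery, dict(patient.artery_mass_fractions))
    return rest_flow_per_gram * patient.myocardial_mass * frac / 60.0


def initialize_coronary_outlets(
    network: VascularNetwork,
    patient: PatientRecord,
    rest_flow_per_gram: float = DEFAULT_REST_FLOW_PER_GRAM,
    splits: Sequence[float] = DEFAULT_RESISTANCE_SPLITS,
    venous_pressure: float = 5.0,
    ca: float = 5e-4,
    cim: float = 5e-3,
    pim_template: Optional[Waveform] = None,
    territory_factors: Optional[Dict[str, float]] = None,
) -> VascularNetwork:
    """Size every coronary outlet from myocardial-mass flow allocation.

    Per-artery rest flow is ``rest_flow_per_gram * myocardial_mass *
    mass_fraction``; among an artery's outlets flow splits proportional to the
    cube of the feeding segment radius (Murray's law). Each outlet's total
    resistance is ``(MAP - venous_pressure) / q_outlet`` and is divided into
    (Ra, Ra_micro, Rv_micro) by `splits`. Returns a parameterized copy.
    """
    splits = tuple(splits)
    if len(splits) != 3 or abs(sum(splits) - 1.0) > 1e-9 or min(splits) <= 0:
        raise ValueError("splits must be three positive fractions summing to 1")
    if territory_factors is None:
        territory_factors = dict(DEFAULT_TERRITORY_FACTORS)
    if pim_template is None:
        pim_template = ventricular_pressure_template()

    net = network.copy()
    net.validate()
    map_ = patient.mean_arterial_pressure
    if map_ <= venous_pressure:
        raise ValueError("mean arterial pressure must exceed venous pressure")

    by_artery: Dict[str, List[str]] = {}
    for node, o in net.outlets.items():
        if isinstance(o, CoronaryOutlet):
            by_artery.setdefault(o.artery, []).append(node)

    pim_cache: Dict[float, Waveform] = {}
    for artery, nodes in by_artery.items():
        q_artery = artery_rest_flow(patient, artery, rest_flow_per_gram)
        radii = []
        for node in nodes:
            seg = net.leaf_segment(node)
            if seg.radius <= 0:
                raise NetworkError(f"zero-radius leaf segment at {node!r}")
            radii.append(seg.radius)
        weights = [r**3 for r in radii]
        wsum = sum(weights)
        tf = territory_factors.get(artery, DEFAULT_TERRITORY_FACTOR)
        if tf not in pim_cache:
            pim_cache[tf] = scale_pim_waveform(pim_template, patient, tf)
        for node, w in zip(nodes, weights):
            q = q_artery * w / wsum
            if q <= 0:
                raise NetworkError(f"non-positive rest flow for outlet {node!r}")
            r_tot = (map_ - venous_pressure) / q
            old = net.outlets[node]
            net.outlets[node] = CoronaryOutlet(
                Ra=splits[0] * r_tot,
                Ca=ca,
                Ra_micro=splits[1] * r_tot,
                Cim=cim,
                Rv_micro=splits[2] * r_tot,
                Pim=pim_cache[tf],
                venous_pressure=venous_pressure,
                artery=old.artery,
            )
    return net


def initialize_systemic_outlet(
    network: VascularNetwork,
    patient: PatientRecord,
    coronary_flow_fraction: float = 0.04,
    rp_fraction: float = 0.06,
    compliance: float = 1.2,
    reference_pressure: float = 0.0,
) -> VascularNetwork:
    """Size the systemic Windkessel from cardiac output and mean pressure.

    Systemic flow is cardiac output times (1 - coronary_flow_fraction);
    ``Rp + Rd = (MAP - reference_pressure) / systemic_flow`` with
    ``Rp = rp_fraction * (Rp + Rd)``. Returns a parameterized copy.
    """
    if not 0 < coronary_flow_fraction < 0.2:
        raise ValueError("coronary_flow_fraction must lie in (0, 0.2)")
    if not 0 < rp_fraction < 1:
        raise ValueError("rp_fraction must lie in (0, 1)")
    co = patient.cardiac_output
    if co <= 0:
        raise ValueError("cardiac output must be positive")
    net = network.copy()
    map_ = patient.mean_arterial_pressure
    q_sys = co * (1.0 - coronary_flow_fraction)
    if map_ <= reference_pressure:
        raise ValueError("MAP must exceed the Windkessel reference pressure")
    r_tot = (map_ - reference_pressure) / q_sys
    done = False
    for node, o in net.outlets.items():
        if isinstance(o, WindkesselOutlet):
            net.outlets[node] = WindkesselOutlet(
                Rp=rp_fraction * r_tot,
                C=compliance,
                Rd=(1.0 - rp_fraction) * r_tot,
                reference_pressure=reference_pressure,
            )
            done = True
    if not done:
        raise NetworkError("network has no Windkessel outlet to initialize")
    return net
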