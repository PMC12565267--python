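"""Parameter tuning against patient targets, and physiological states.

Initial outlet parameters come from simple Ohm-analogy quotients of patient
pressures and allocated flows; the periodic solve of the assembled network
then deviates from the targets (pulsatility, stenosis losses, inter-outlet
coupling). ``tune_parameters`` closes the loop with proportional fixed-point
updates: after each periodic solve, every coronary outlet's total resistance
is scaled by (simulated/target mean flow), the systemic resistance by the
MAP mismatch, and the systemic compliance by the pulse-pressure mismatch.

Physiological states are represented multiplicatively: hyperemia (adenosine)
divides the coronary *microvascular* resistances (Ra_micro, Rv_micro) by
~4x (factor 0.24) while leaving the epicardial Ra and the compliances
untouched; an exercise state additionally raises heart rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .network import (
    CoronaryOutlet,
    VascularNetwork,
    WindkesselOutlet,
    artery_rest_flow,
)
from .solver import SimulationResult, SolverSettings, run_to_periodic
from .waveforms import PatientRecord, Waveform

__all__ = [
    "TuningTargets",
    "PhysiologicalState",
    "REST",
    "HYPEREMIA",
    "EXERCISE",
    "targets_from_patient",
    "tune_parameters",
    "apply_state",
    "rescale_inflow_heart_rate",
]


@dataclass(frozen=True)
class TuningTargets:
    """Pressure and per-artery flow targets for lumped-parameter refinement."""

    mean_aortic_pressure: float  # mmHg
    systolic_pressure: float  # mmHg
    diastolic_pressure: float  # mmHg
    artery_flows: Dict[str, float] = field(default_factory=dict)  # mL/s, mean
    tolerance: float = 0.05  # relative, per target

    def __post_init__(self):
        if not 0 < self.tolerance <= 0.2:
            raise ValueError("tolerance must lie in (0, 0.2]")
        if min(self.mean_aortic_pressure, self.systolic_pressure,
               self.diastolic_pressure) <= 0:
            raise ValueError("pressure targets must be positive")
        if self.systolic_pressure <= self.diastolic_pressure:
            raise ValueError("systolic target must exceed diastolic target")
        if any(q <= 0 for q in self.artery_flows.values()):
            raise ValueError("artery flow targets must be positive")

    @property
    def pulse_pressure(self) -> float:
        return self.systolic_pressure - self.diastolic_pressure


def targets_from_patient(patient: PatientRecord, network: VascularNetwork,
                         rest_flow_per_gram: float = 0.8,
                         tolerance: float = 0.05) -> TuningTargets:
    """Rest tuning targets from the patient record and the network's arteries."""
    flows = {
        artery: artery_rest_flow(patient, artery, rest_flow_per_gram)
        for artery in network.coronary_arteries()
    }
    return TuningTargets(
        mean_aortic_pressure=patient.mean_arterial_pressure,
        systolic_pressure=patient.systolic_pressure,
        diastolic_pressure=patient.diastolic_pressure,
        artery_flows=flows,
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class PhysiologicalState:
    """A multiplicative modifier of the rest network.

    microvascular_resistance_factor scales coronary Ra_micro and Rv_micro;
    heart_rate_factor scales heart rate (inflow re-scaled to preserve stroke
    volume). Rest is the identity (both factors 1).
    """

    label: str
    microvascular_resistance_factor: float = 1.0
    heart_rate_factor: float = 1.0

    def __post_init__(self):
        if self.microvascular_resistance_factor <= 0:
            raise ValueError("microvascular_resistance_factor must be positive")
        if self.heart_rate_factor <= 0:
            raise ValueError("heart_rate_factor must be positive")


REST = PhysiologicalState("rest", 1.0, 1.0)
#: adenosine-type maximal vasodilation: microvascular resistance to 24 percent
HYPEREMIA = PhysiologicalState("hyperemia", 0.24, 1.0)
#: moderate exercise: partial vasodilation plus chronotropic response
EXERCISE = PhysiologicalState("exercise", 0.5, 1.5)


def apply_state(network: VascularNetwork, state: PhysiologicalState,
                inflow: Optional[Waveform] = None):
    """Return the network (and optionally inflow) under a physiological state.

    Coronary Ra_micro and Rv_micro are multiplied by the state's
    microvascular factor; the rest state returns the inputs unchanged. When
    an inflow is given, it is time-compressed by the heart-rate factor with
    its per-beat volume (stroke volume) preserved, and (network, inflow) is
    returned.
    """
    if state.label == "rest" or (
        state.microvascular_resistance_factor == 1.0
        and state.heart_rate_factor == 1.0
    ):
        return (network, inflow) if inflow is not None else network
    net = network.copy()
    f = state.microvascular_resistance_factor
    for node, o in net.outlets.items():
        if isinstance(o, CoronaryOutlet):
            o.Ra_micro = o.Ra_micro * f
            o.Rv_micro = o.Rv_micro * f
    if inflow is None:
        return net
    return net, rescale_inflow_heart_rate(inflow, state.heart_rate_factor)


def rescale_inflow_heart_rate(inflow: Waveform, heart_rate_factor: float) -> Waveform:
    """Compress the cycle by the heart-rate factor, preserving stroke volume.

    Times shrink by 1/factor and values grow by factor, so the per-beat
    integral is unchanged while beats come factor times as often.
    """
    if heart_rate_factor <= 0:
        raise ValueError("heart_rate_factor must be positive")
    if heart_rate_factor == 1.0:
        return inflow
    return Waveform(
        inflow.times / heart_rate_factor,
        inflow.values * heart_rate_factor,
        inflow.period / heart_rate_factor,
    )


def _measure(result: SimulationResult, network: VascularNetwork,
             root: str) -> Tuple[float, float, Dict[str, float]]:
    """Simulated MAP, pulse pressure at the root, and per-artery mean flows."""
    map_sim = result.mean_pressure(root)
    pp_sim = result.pulse_pressure(root)
    flows: Dict[str, float] = {}
    for node, o in network.outlets.items():
        if isinstance(o, CoronaryOutlet):
            seg = network.leaf_segment(node)
            flows[o.artery] = flows.get(o.artery, 0.0) + result.mean_flow(seg.id)
    return map_sim, pp_sim, flows


def tune_parameters(
    network: VascularNetwork,
    inflow: Waveform,
    targets: TuningTargets,
    settings: Optional[SolverSettings] = None,
    max_iterations: int = 25,
) -> Tuple[VascularNetwork, dict]:
    """Refine outlet parameters until pressure/flow targets are met.

    Proportional fixed-point updates per iteration (see module docstring).
    Returns the tuned network and a report with per-iteration errors and
    parameter values; if the iteration cap is hit, the report is flagged
    non-converged and the best iterate (smallest maximum relative error) is
    returned.
    """
    if settings is None:
        settings = SolverSettings()
    net = network.copy()
    net.validate()
    root = net.inflow_node
    # feasibility: target MAP must exceed every outlet's back pressure
    for o in net.outlets.values():
        back = o.reference_pressure if isinstance(o, WindkesselOutlet) else o.venous_pressure
        if targets.mean_aortic_pressure <= back:
            raise ValueError(
                "target mean aortic pressure does not exceed the outlet "
                f"back pressure ({back} mmHg): infeasible targets"
            )
    missing = [a for a in targets.artery_flows if a not in net.coronary_arteries()]
    if missing:
        raise ValueError(f"flow targets for unknown arteries: {missing}")

    iterations = []
    best = (math.inf, net.copy(), None)
    warm_state = None
    for it in range(max_iterations):
        result = run_to_periodic(net, inflow, settings, state_label="tuning",
                                 initial_state=warm_state)
        warm_state = result.final_state
        map_sim, pp_sim, flows_sim = _measure(result, net, root)
        errors = {
            "mean_aortic_pressure": abs(map_sim - targets.mean_aortic_pressure)
            / targets.mean_aortic_pressure,
            "pulse_pressure": abs(pp_sim - targets.pulse_pressure)
            / targets.pulse_pressure,
        }
        for artery, q_t in targets.artery_flows.items():
            errors[f"flow:{artery}"] = abs(flows_sim.get(artery, 0.0) - q_t) / q_t
        max_err = max(errors.values())
        iterations.append(
            {
                "iteration": it + 1,
                "simulated": {
                    "mean_aortic_pressure": map_sim,
                    "pulse_pressure": pp_sim,
                    "artery_flows": flows_sim,
                },
                "errors": errors,
                "max_error": max_err,
            }
        )
        if max_err < best[0]:
            best = (max_err, net.copy(), warm_state)
        if max_err <= targets.tolerance:
            report = {
                "converged": True,
                "iterations": iterations,
                "final_max_error": max_err,
            }
            return net, report

        # proportional updates
        for node, o in list(net.outlets.items()):
            if isinstance(o, WindkesselOutlet):
                r_tot = o.Rp + o.Rd
                scale_r = (targets.mean_aortic_pressure - o.reference_pressure) / max(
                    map_sim - o.reference_pressure, 1e-9
                )
                rp_frac = o.Rp / r_tot
                r_new = r_tot * scale_r
                scale_c = pp_sim / targets.pulse_pressure
                net.outlets[node] = WindkesselOutlet(
                    Rp=rp_frac * r_new,
                    C=o.C * scale_c,
                    Rd=(1 - rp_frac) * r_new,
                    reference_pressure=o.reference_pressure,
                )
            else:
                q_t = targets.artery_flows.get(o.artery)
                if q_t is None:
                    continue
                # the artery's outlets share one flow target; scale each by the
                # artery-level mismatch so the split is preserved
                scale = flows_sim.get(o.artery, 0.0) / q_t
                if scale <= 0:
                    scale = 0.5  # no simulated flow: halve resistance and retry
                net.outlets[node] = CoronaryOutlet(
                    Ra=o.Ra * scale,
                    Ca=o.Ca,
                    Ra_micro=o.Ra_micro * scale,
                    Cim=o.Cim,
                    Rv_micro=o.Rv_micro * scale,
                    Pim=o.Pim,
                    venous_pressure=o.venous_pressure,
                    artery=o.artery,
                )

    report = {
        "converged": False,
        "iterations": iterations,
        "final_max_error": best[0],
    }
    return best[1], report
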