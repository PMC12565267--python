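"""A bundled single-patient fixture: typical hemodynamics, aorta + two
coronary branches (stenosed LAD, plain RCA). Generated in code so nothing is
shipped as data; used by the `demo` CLI command and the test suite."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .network import (
    CoronaryOutlet,
    Stenosis,
    VascularNetwork,
    VesselSegment,
    WindkesselOutlet,
    initialize_coronary_outlets,
    initialize_systemic_outlet,
)
from .waveforms import PatientRecord, Waveform

__all__ = ["demo_patient", "demo_network", "write_demo_inputs"]


def demo_patient() -> PatientRecord:
    return PatientRecord(
        heart_rate=70.0,
        systolic_pressure=120.0,
        diastolic_pressure=80.0,
        stroke_volume=75.0,
        systolic_ejection_time=0.31,
        body_surface_area=1.9,
        myocardial_mass=130.0,
        artery_mass_fractions={"LAD": 0.45, "LCx": 0.25, "RCA": 0.25, "LM": 0.05},
    )


def demo_network(percent_stenosis: float = 55.0,
                 initialize: bool = True,
                 patient: PatientRecord | None = None) -> VascularNetwork:
    """Aorta + systemic Windkessel + stenosed LAD + plain RCA."""
    rref = 0.17
    rmin = rref * (1.0 - percent_stenosis / 100.0)
    placeholder_pim = Waveform(np.linspace(0.0, 1.0, 17), np.zeros(17), 1.0)
    segments = [
        VesselSegment("ao_root", "inlet", "ao_arch", 4.0, 1.2),
        VesselSegment("ao_desc", "ao_arch", "sys", 8.0, 1.1),
        VesselSegment("LAD_prox", "ao_arch", "LAD_n1", 2.0, rref),
        VesselSegment("LAD_lesion", "LAD_n1", "LAD_n2", 1.8, rref),
        VesselSegment("LAD_dist", "LAD_n2", "LAD_leaf", 2.5, 0.9 * rref),
        VesselSegment("RCA_prox", "ao_arch", "RCA_n1", 3.0, 0.16),
        VesselSegment("RCA_dist", "RCA_n1", "RCA_leaf", 2.5, 0.14),
    ]
    stenoses = [
        Stenosis("LAD_lesion", reference_radius=rref, minimal_lumen_radius=rmin,
                 lesion_length=1.8)
    ]
    outlets = {
        "sys": WindkesselOutlet(Rp=0.1, C=1.2, Rd=1.0),
        "LAD_leaf": CoronaryOutlet(Ra=1.0, Ca=5e-4, Ra_micro=1.0, Cim=5e-3,
                                   Rv_micro=1.0, Pim=placeholder_pim,
                                   artery="LAD"),
        "RCA_leaf": CoronaryOutlet(Ra=1.0, Ca=5e-4, Ra_micro=1.0, Cim=5e-3,
                                   Rv_micro=1.0, Pim=placeholder_pim,
                                   artery="RCA"),
    }
    net = VascularNetwork(segments=segments, stenoses=stenoses, outlets=outlets,
                          inflow_node="inlet")
    if initialize:
        pat = patient or demo_patient()
        net = initialize_systemic_outlet(net, pat)
        net = initialize_coronary_outlets(net, pat)
    return net


def write_demo_inputs(outdir) -> None:
    """Write patient.json and network.json for the demo pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "patient.json").write_text(
        json.dumps(demo_patient().to_dict(), indent=2) + "\n"
    )
    demo_network(initialize=False).to_json(outdir / "network.json")
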