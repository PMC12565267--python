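"""Reproducible synthetic patients and coronary lesions.

The generator emulates the lesion population of a chronic-coronary-syndrome
cohort: diameter stenosis 55.3 +/- 11.2 % restricted to the significant range
[40, 80] %, lesion length 18.0 +/- 7.4 mm, and lesions distributed over
LAD/LCx/RCA/LM with probabilities 0.49/0.26/0.22/0.03. Stenosis percent and
length are drawn from truncated normals whose parent parameters are solved by
moment matching, so the *truncated* distribution reproduces the stated sample
mean and SD (a reported cohort mean is a post-truncation moment; using it as
the parent mean would bias the sample mean upward by ~1.5 points).

Patient hemodynamics (heart rate, pressures, stroke volume, BSA, myocardial
mass, per-artery mass fractions) use conventional physiological distributions;
they are synthetic conventions, fully configurable, not cohort facts.

Ground-truth revascularization labels come from an oracle FFR: a
finer-tolerance re-solve of the hyperemic state plus Gaussian measurement
noise, thresholded at 0.80. This emulates a heterogeneous clinical decision
basis (pressure-wire FFR, perfusion imaging, ECG/wall motion) as a single
noise scale on the functional ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .indices import DEFAULT_ROI_LENGTH, compute_ffr, compute_lesion_indices
from .network import (
    CoronaryOutlet,
    Stenosis,
    VascularNetwork,
    VesselSegment,
    WindkesselOutlet,
    initialize_coronary_outlets,
    initialize_systemic_outlet,
)
from .solver import SolverSettings, run_to_periodic
from .tuning import HYPEREMIA, PhysiologicalState, apply_state
from .waveforms import PatientRecord, Waveform, aortic_flow_template, scale_inflow_waveform

__all__ = [
    "TruncatedNormalSpec",
    "CohortSpec",
    "LesionCase",
    "sample_cohort",
    "assign_labels",
    "simulate_lesion",
    "COHORT_SOLVER_SETTINGS",
]

#: solver settings for cohort sweeps: coarser output grid and integrator
#: tolerance (FFR unchanged to 4 decimals vs the defaults), same physics
COHORT_SOLVER_SETTINGS = SolverSettings(time_step=5e-3, max_cycles=16,
                                        periodicity_tolerance=1e-3,
                                        rtol=1e-5, atol=1e-4)


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """A truncated normal stated by its observed (post-truncation) moments."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.mean < self.high:
            raise ValueError("mean must lie inside (low, high)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def frozen(self):
        """The scipy truncnorm whose truncated moments best match mean/sd.

        Parent (mu, sigma) are found by least squares on the relative moment
        mismatch; when the requested sd exceeds what the family supports on
        [low, high], the closest attainable sd is used.
        """
        target_m, target_s = self.mean, self.sd

        def resid(p):
            mu, log_sigma = p
            sigma = math.exp(log_sigma)
            a = (self.low - mu) / sigma
            b = (self.high - mu) / sigma
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            return [(m - target_m) / target_m, (math.sqrt(v) - target_s) / target_s]

        sol = optimize.least_squares(
            resid, x0=[target_m, math.log(target_s)], xtol=1e-12, ftol=1e-12
        )
        mu, sigma = sol.x[0], math.exp(sol.x[1])
        a = (self.low - mu) / sigma
        b = (self.high - mu) / sigma
        return stats.truncnorm(a, b, loc=mu, scale=sigma)

    def sample(self, rng: np.random.Generator, size=None):
        return self.frozen().rvs(size=size, random_state=rng)


#: reference lumen radius (cm) distributions by artery: (mean, sd, low, high)
DEFAULT_ARTERY_RADII = {
    "LAD": (0.17, 0.02, 0.13, 0.24),
    "LCx": (0.16, 0.02, 0.125, 0.22),
    "RCA": (0.17, 0.02, 0.13, 0.24),
    "LM": (0.23, 0.02, 0.18, 0.30),
}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw a reproducible synthetic lesion cohort."""

    seed: int
    n_patients: int = 64
    max_lesions: Optional[int] = None
    lesions_per_patient: Dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.35, 3: 0.15}
    )
    stenosis_percent: TruncatedNormalSpec = TruncatedNormalSpec(55.3, 11.2, 40.0, 80.0)
    lesion_length_mm: TruncatedNormalSpec = TruncatedNormalSpec(18.0, 7.4, 4.0, 40.0)
    artery_probabilities: Dict[str, float] = field(
        default_factory=lambda: {"LAD": 0.49, "LCx": 0.26, "RCA": 0.22, "LM": 0.03}
    )
    heart_rate: TruncatedNormalSpec = TruncatedNormalSpec(70.0, 10.0, 45.0, 110.0)
    systolic_pressure: TruncatedNormalSpec = TruncatedNormalSpec(130.0, 15.0, 95.0, 185.0)
    diastolic_pressure: TruncatedNormalSpec = TruncatedNormalSpec(78.0, 10.0, 50.0, 105.0)
    stroke_volume: TruncatedNormalSpec = TruncatedNormalSpec(75.0, 12.0, 40.0, 120.0)
    body_surface_area: TruncatedNormalSpec = TruncatedNormalSpec(1.85, 0.2, 1.3, 2.5)
    myocardial_mass: TruncatedNormalSpec = TruncatedNormalSpec(130.0, 25.0, 70.0, 220.0)
    mass_fraction_alpha: Tuple[float, ...] = (27.0, 15.0, 15.0, 3.0)  # LAD,LCx,RCA,LM
    label_threshold: float = 0.80
    measurement_noise_sd: float = 0.03

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible cohorts")
        total = sum(self.artery_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("artery_probabilities must sum to 1")
        if abs(sum(self.lesions_per_patient.values()) - 1.0) > 1e-9:
            raise ValueError("lesions_per_patient probabilities must sum to 1")
        if not 0 < self.label_threshold <= 1.0:
            raise ValueError("label_threshold must lie in (0, 1]")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be non-negative")


@dataclass
class LesionCase:
    """One simulated lesion: patient context plus its single-artery network."""

    patient_id: int
    lesion_id: str
    artery: str
    patient: PatientRecord
    network: Optional[VascularNetwork]  # rest-initialized, stenosis included
    stenosis: Stenosis


def _sample_patient(rng: np.random.Generator, spec: CohortSpec,
                    dists: dict) -> PatientRecord:
    hr = float(dists["heart_rate"].rvs(random_state=rng))
    sys_p = float(dists["systolic_pressure"].rvs(random_state=rng))
    dia = float(dists["diastolic_pressure"].rvs(random_state=rng))
    dia = min(dia, sys_p - 25.0)  # keep a plausible pulse pressure
    sv = float(dists["stroke_volume"].rvs(random_state=rng))
    bsa = float(dists["body_surface_area"].rvs(random_state=rng))
    mass = float(dists["myocardial_mass"].rvs(random_state=rng))
    fracs = rng.dirichlet(spec.mass_fraction_alpha)
    period = 60.0 / hr
    # systolic ejection time: rate-corrected, clipped inside the cycle
    set_ = min(0.33 * math.sqrt(period), 0.45 * period)
    return PatientRecord(
        heart_rate=hr,
        systolic_pressure=sys_p,
        diastolic_pressure=dia,
        stroke_volume=sv,
        systolic_ejection_time=set_,
        body_surface_area=bsa,
        myocardial_mass=mass,
        artery_mass_fractions=dict(zip(("LAD", "LCx", "RCA", "LM"), fracs)),
    )


def build_lesion_network(artery: str, reference_radius: float,
                         percent_stenosis: float, lesion_length_cm: float,
                         distal_length_cm: float = 2.5) -> VascularNetwork:
    """Aorta + systemic Windkessel + one stenosed coronary branch.

    Outlets are placeholders; initialize_* functions size them per patient.
    The distal segment is at least the WSS region of interest (1.5 cm) plus
    margin so ROI metrics never truncate.
    """
    r_min = reference_radius * (1.0 - percent_stenosis / 100.0)
    segs = [
        VesselSegment("ao_root", "inlet", "ao_arch", 4.0, 1.2),
        VesselSegment("ao_desc", "ao_arch", "sys", 8.0, 1.1),
        VesselSegment(f"{artery}_prox", "ao_arch", f"{artery}_n1", 2.0,
                      reference_radius),
        VesselSegment(f"{artery}_lesion", f"{artery}_n1", f"{artery}_n2",
                      lesion_length_cm, reference_radius),
        VesselSegment(f"{artery}_dist", f"{artery}_n2", f"{artery}_leaf",
                      distal_length_cm, 0.9 * reference_radius),
    ]
    stenosis = Stenosis(
        segment_id=f"{artery}_lesion",
        reference_radius=reference_radius,
        minimal_lumen_radius=r_min,
        lesion_length=lesion_length_cm,
    )
    placeholder_pim = Waveform(np.linspace(0.0, 1.0, 17), np.zeros(17), 1.0)
    outlets = {
        "sys": WindkesselOutlet(Rp=0.1, C=1.2, Rd=1.0),
        f"{artery}_leaf": CoronaryOutlet(
            Ra=1.0, Ca=5e-4, Ra_micro=1.0, Cim=5e-3, Rv_micro=1.0,
            Pim=placeholder_pim, artery=artery,
        ),
    }
    return VascularNetwork(segments=segs, stenoses=[stenosis], outlets=outlets,
                           inflow_node="inlet")


def sample_cohort(spec: CohortSpec, build_networks: bool = True) -> List[LesionCase]:
    """Draw the cohort; deterministic given the spec (seed included).

    With ``build_networks=False`` only patients and lesion geometry are drawn
    (LesionCase.network is None); the random stream is identical either way,
    so geometry statistics can be checked cheaply.
    """
    rng = np.random.default_rng(spec.seed)
    dists = {
        name: getattr(spec, name).frozen()
        for name in (
            "heart_rate",
            "systolic_pressure",
            "diastolic_pressure",
            "stroke_volume",
            "body_surface_area",
            "myocardial_mass",
            "stenosis_percent",
            "lesion_length_mm",
        )
    }
    radius_dists = {
        artery: TruncatedNormalSpec(*params).frozen()
        for artery, params in DEFAULT_ARTERY_RADII.items()
    }
    arteries = list(spec.artery_probabilities)
    artery_p = np.array([spec.artery_probabilities[a] for a in arteries])
    counts = np.array(sorted(spec.lesions_per_patient))
    count_p = np.array([spec.lesions_per_patient[c] for c in counts])

    cases: List[LesionCase] = []
    for pid in range(spec.n_patients):
        if spec.max_lesions is not None and len(cases) >= spec.max_lesions:
            break
        patient = _sample_patient(rng, spec, dists)
        n_lesions = int(rng.choice(counts, p=count_p))
        # arteries drawn independently per lesion so the marginal matches the
        # stated distribution; two lesions in one artery are analyzed as
        # separate single-stenosis cases
        chosen = rng.choice(len(arteries), size=n_lesions, p=artery_p)
        for j, ai in enumerate(np.atleast_1d(chosen)):
            artery = arteries[int(ai)]
            pct = float(dists["stenosis_percent"].rvs(random_state=rng))
            length_cm = float(dists["lesion_length_mm"].rvs(random_state=rng)) / 10.0
            radius = float(radius_dists[artery].rvs(random_state=rng))
            if build_networks:
                net = build_lesion_network(artery, radius, pct, length_cm)
                net = initialize_systemic_outlet(net, patient)
                net = initialize_coronary_outlets(net, patient)
                stenosis = net.stenoses[0]
            else:
                net = None
                stenosis = Stenosis(
                    segment_id=f"{artery}_lesion",
                    reference_radius=radius,
                    minimal_lumen_radius=radius * (1.0 - pct / 100.0),
                    lesion_length=length_cm,
                )
            cases.append(
                LesionCase(
                    patient_id=pid,
                    lesion_id=f"p{pid:03d}_{j}_{artery}",
                    artery=artery,
                    patient=patient,
                    network=net,
                    stenosis=stenosis,
                )
            )
            if spec.max_lesions is not None and len(cases) >= spec.max_lesions:
                break
    return cases


def simulate_lesion(
    case: LesionCase,
    settings: SolverSettings = COHORT_SOLVER_SETTINGS,
    state: PhysiologicalState = HYPEREMIA,
    roi_length: float = DEFAULT_ROI_LENGTH,
    reference_refine: float = 4.0,
) -> dict:
    """Hyperemic solve + indices + finer-tolerance oracle FFR for one lesion."""
    inflow = scale_inflow_waveform(aortic_flow_template(), case.patient)
    hyper_net = apply_state(case.network, state)
    result = run_to_periodic(hyper_net, inflow, settings, state_label="hyperemia")
    idx = compute_lesion_indices(result, hyper_net, case.stenosis,
                                 roi_length=roi_length)
    ref_result = run_to_periodic(
        hyper_net, inflow, settings.refined(reference_refine),
        state_label="hyperemia", initial_state=result.final_state,
    )
    reference_ffr = compute_ffr(ref_result, hyper_net, case.stenosis)
    return {
        "patient_id": case.patient_id,
        "lesion_id": case.lesion_id,
        "artery": case.artery,
        "percent_stenosis": case.stenosis.percent_stenosis,
        "lesion_length_mm": case.stenosis.lesion_length * 10.0,
        "reference_radius_cm": case.stenosis.reference_radius,
        "ffr_cfd": idx.ffr_cfd,
        "delta_p_mmHg": idx.delta_p,
        "hapv_cm_s": idx.hapv,
        "chsr": idx.chsr,
        "tawss_pa": idx.tawss,
        "osi": idx.osi,
        "reference_ffr": reference_ffr,
        "converged": result.converged and ref_result.converged,
    }


def assign_labels(
    cases: List[LesionCase],
    label_threshold: float = 0.80,
    measurement_noise_sd: float = 0.03,
    settings: SolverSettings = COHORT_SOLVER_SETTINGS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate every lesion and attach noisy oracle-FFR labels.

    label = 1 iff reference_ffr + noise <= label_threshold, where
    reference_ffr comes from the finer-tolerance hyperemic solve and noise is
    N(0, measurement_noise_sd). One row per lesion.
    """
    rows = [simulate_lesion(case, settings) for case in cases]
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, measurement_noise_sd, size=len(df))
        if measurement_noise_sd > 0
        else np.zeros(len(df))
    )
    df["reference_ffr_measured"] = df["reference_ffr"] + noise
    df["label"] = (df["reference_ffr_measured"] <= label_threshold).astype(int)
    return df
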