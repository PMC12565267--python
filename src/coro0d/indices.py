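"""Per-lesion functional indices and wall-shear metrics.

From a periodic hyperemic simulation this module computes, per lesion:

* FFR_CFD = time-averaged distal pressure / time-averaged aortic pressure;
* delta_P = mean translesional pressure gradient (mmHg);
* hAPV = hyperemic average peak velocity at the minimal lumen (cm/s),
  using the parabolic-profile peak (twice the mean cross-sectional velocity);
* cHSR = delta_P / hAPV (mmHg per cm/s), the computational hyperemic
  stenosis resistance index;
* TAWSS and OSI over a region of interest distal to the stenosis, from
  Poiseuille wall shear tau(t) = 4*mu*Q(t)/(pi*r^3) per segment.

TAWSS = (1/T) * integral |tau| dt   (Pa)
OSI   = 0.5 * (1 - |integral tau dt| / integral |tau| dt)   in [0, 0.5]
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .network import (
    BLOOD_VISCOSITY,
    Stenosis,
    VascularNetwork,
    VesselSegment,
)
from .solver import SimulationResult

__all__ = [
    "LesionIndices",
    "compute_ffr",
    "compute_delta_p",
    "compute_hapv",
    "compute_chsr",
    "compute_tawss",
    "compute_osi",
    "segment_wss_series",
    "roi_metrics",
    "compute_lesion_indices",
    "indices_table",
]

#: dyn/cm^2 -> Pa
DYN_CM2_TO_PA = 0.1
#: default region of interest beyond the stenosis, cm (15 mm)
DEFAULT_ROI_LENGTH = 1.5


@dataclass(frozen=True)
class LesionIndices:
    """The per-lesion index panel."""

    ffr_cfd: float  # dimensionless, (0, 1] for an aorta-fed lesion
    delta_p: float  # mmHg, mean hyperemic translesional gradient
    hapv: float  # cm/s
    chsr: float  # mmHg/(cm/s); always delta_p / hapv
    tawss: float  # Pa
    osi: float  # dimensionless in [0, 0.5]
    roi_length: float  # cm

    def __post_init__(self):
        if self.hapv > 0:
            assert math.isclose(self.chsr, self.delta_p / self.hapv, rel_tol=1e-12)


def _require_hyperemic(result: SimulationResult, allow_rest: bool, what: str):
    if result.state_label != "hyperemia" and not allow_rest:
        raise ValueError(
            f"{what} is defined under hyperemia; got a "
            f"{result.state_label or 'unlabeled'!s} result "
            "(pass allow_rest=True to override)"
        )
    if result.state_label != "hyperemia" and allow_rest:
        warnings.warn(
            f"{what} computed from a non-hyperemic result", stacklevel=3
        )


def _time_mean(series: np.ndarray, times: np.ndarray) -> float:
    return float(np.trapezoid(series, times) / (times[-1] - times[0]))


def compute_ffr(
    result: SimulationResult,
    network: VascularNetwork,
    lesion: Stenosis,
    aortic_node: Optional[str] = None,
    allow_rest: bool = False,
) -> float:
    """FFR_CFD: ratio of mean distal to mean aortic pressure over one cycle.

    The distal node is the node immediately downstream of the lesion segment;
    the aortic node defaults to the network's inflow node.
    """
    _require_hyperemic(result, allow_rest, "FFR_CFD")
    if aortic_node is None:
        aortic_node = network.inflow_node
    seg = network.segment_by_id(lesion.segment_id)
    pd_mean = _time_mean(result.node_pressures[seg.distal_node], result.times)
    pa_mean = _time_mean(result.node_pressures[aortic_node], result.times)
    if pa_mean <= 0:
        raise ValueError("non-positive mean aortic pressure")
    return pd_mean / pa_mean


def compute_delta_p(
    result: SimulationResult,
    network: VascularNetwork,
    lesion: Stenosis,
    allow_rest: bool = False,
) -> float:
    """Mean translesional pressure gradient (proximal minus distal), mmHg."""
    _require_hyperemic(result, allow_rest, "delta_P")
    seg = network.segment_by_id(lesion.segment_id)
    p_prox = _time_mean(result.node_pressures[seg.proximal_node], result.times)
    p_dist = _time_mean(result.node_pressures[seg.distal_node], result.times)
    return p_prox - p_dist


def compute_hapv(
    result: SimulationResult,
    lesion: Stenosis,
    allow_rest: bool = False,
) -> float:
    """Hyperemic average peak velocity at the minimal lumen, cm/s.

    The instantaneous peak velocity assumes a parabolic profile,
    v_peak(t) = 2*Q(t)/As with Q in mL/s and As = pi*r_min^2 in cm^2;
    hAPV is its time average over the final cycle.
    """
    _require_hyperemic(result, allow_rest, "hAPV")
    a_s = lesion.minimal_lumen_area
    if a_s <= 0:
        raise ValueError("zero minimal lumen area")
    q = result.segment_flows[lesion.segment_id]
    v_peak = 2.0 * q / a_s
    return _time_mean(v_peak, result.times)


def compute_chsr(delta_p: float, hapv: float) -> float:
    """cHSR = delta_P / hAPV, mmHg per cm/s."""
    if hapv <= 0:
        raise ValueError("hAPV must be positive to form cHSR")
    return delta_p / hapv


def compute_tawss(wss_series: np.ndarray, period: float,
                  times: Optional[np.ndarray] = None) -> float:
    """Time-averaged wall shear stress magnitude, (1/T) * integral |tau| dt."""
    wss_series = np.asarray(wss_series, dtype=float)
    if wss_series.size == 0:
        raise ValueError("empty WSS series")
    if times is None:
        times = np.linspace(0.0, period, wss_series.size)
    return float(np.trapezoid(np.abs(wss_series), times) / period)


def compute_osi(wss_series: np.ndarray, period: float,
                times: Optional[np.ndarray] = None) -> float:
    """Oscillatory shear index, 0.5 * (1 - |int tau| / int |tau|).

    0 for a signal that never changes sign; 0.5 for a zero-mean signal. An
    identically zero series returns 0 with a warning (the quotient is
    undefined).
    """
    wss_series = np.asarray(wss_series, dtype=float)
    if wss_series.size == 0:
        raise ValueError("empty WSS series")
    if times is None:
        times = np.linspace(0.0, period, wss_series.size)
    num = abs(np.trapezoid(wss_series, times))
    den = np.trapezoid(np.abs(wss_series), times)
    if den == 0.0:
        warnings.warn("OSI of an identically zero WSS series; defining OSI = 0",
                      stacklevel=2)
        return 0.0
    osi = 0.5 * (1.0 - num / den)
    # clip pure floating-point spill only
    if -1e-12 <= osi < 0.0:
        osi = 0.0
    elif 0.5 < osi <= 0.5 + 1e-12:
        osi = 0.5
    return float(osi)


def segment_wss_series(
    result: SimulationResult,
    network: VascularNetwork,
    segment: VesselSegment,
    viscosity: float = BLOOD_VISCOSITY,
) -> np.ndarray:
    """Poiseuille wall shear stress series of a segment, Pa (signed by flow).

    tau(t) = 4*mu*Q(t)/(pi*r^3), with Q in mL/s and r in cm, converted from
    dyn/cm^2 to Pa.
    """
    if segment.radius <= 0:
        raise ValueError("zero segment radius")
    q = result.segment_flows[segment.id]
    return 4.0 * viscosity * q / (math.pi * segment.radius**3) * DYN_CM2_TO_PA


def _downstream_spans(network: VascularNetwork, start_node: str,
                      roi_length: float) -> List[Tuple[VesselSegment, float]]:
    """(segment, included length) pairs within roi_length distal of start_node."""
    children = network.children()
    spans: List[Tuple[VesselSegment, float]] = []
    stack = [(start_node, 0.0)]
    while stack:
        node, used = stack.pop()
        for seg in children.get(node, []):
            take = min(seg.length, roi_length - used)
            if take > 0:
                spans.append((seg, take))
            if used + seg.length < roi_length:
                stack.append((seg.distal_node, used + seg.length))
    return spans


def roi_metrics(
    result: SimulationResult,
    network: VascularNetwork,
    lesion: Stenosis,
    roi_length: float = DEFAULT_ROI_LENGTH,
    viscosity: float = BLOOD_VISCOSITY,
) -> Tuple[float, float]:
    """Length-weighted (TAWSS, OSI) over the region beyond the stenosis.

    WSS series are gathered over the segments within ``roi_length`` (default
    1.5 cm) distal to the lesion's minimal-lumen location; per-segment TAWSS
    and OSI are averaged weighted by the included length.
    """
    if roi_length <= 0:
        raise ValueError("roi_length must be positive")
    seg = network.segment_by_id(lesion.segment_id)
    spans = _downstream_spans(network, seg.distal_node, roi_length)
    if not spans:
        warnings.warn(
            "lesion has no downstream vessel length; ROI metrics computed "
            "over the lesion segment itself",
            stacklevel=2,
        )
        spans = [(seg, seg.length)]
    period = result.period
    total = sum(w for _, w in spans)
    tawss = 0.0
    osi = 0.0
    for s, w in spans:
        tau = segment_wss_series(result, network, s, viscosity)
        tawss += w * compute_tawss(tau, period, result.times)
        osi += w * compute_osi(tau, period, result.times)
    return tawss / total, osi / total


def compute_lesion_indices(
    result: SimulationResult,
    network: VascularNetwork,
    lesion: Stenosis,
    aortic_node: Optional[str] = None,
    roi_length: float = DEFAULT_ROI_LENGTH,
    viscosity: float = BLOOD_VISCOSITY,
    allow_rest: bool = False,
) -> LesionIndices:
    """The full per-lesion panel from one hyperemic periodic solve."""
    ffr = compute_ffr(result, network, lesion, aortic_node, allow_rest)
    dp = compute_delta_p(result, network, lesion, allow_rest=True)
    hapv = compute_hapv(result, lesion, allow_rest=True)
    chsr = compute_chsr(dp, hapv)
    tawss, osi = roi_metrics(result, network, lesion, roi_length, viscosity)
    return LesionIndices(
        ffr_cfd=ffr, delta_p=dp, hapv=hapv, chsr=chsr, tawss=tawss, osi=osi,
        roi_length=roi_length,
    )


def indices_table(rows: List[dict]) -> pd.DataFrame:
    """Assemble the per-lesion indices CSV table with canonical columns."""
    cols = [
        "lesion_id",
        "artery",
        "percent_stenosis",
        "ffr_cfd",
        "delta_p_mmHg",
        "hapv_cm_s",
        "chsr",
        "tawss_pa",
        "osi",
    ]
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in cols]
    return df[[c for c in cols if c in df.columns] + extra]
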