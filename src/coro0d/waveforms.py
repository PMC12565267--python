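"""Periodic waveforms driving the simulation, and the patient record that scales them.

The simulator is forced by two periodic signals per cardiac cycle of duration
``T = 60 / heart_rate``:

* an aortic inflow waveform Q(t) in mL/s whose integral over one cycle is the
  stroke volume, with a positive-flow (ejection) window equal to the patient's
  systolic ejection time;
* an intramyocardial pressure waveform Pim(t) in mmHg compressing the coronary
  microcirculation, whose peak tracks a fraction of the patient's systolic
  pressure (full compression for left-ventricular territories, reduced for the
  right coronary territory).

Template shapes are normalized (unit period; unit stroke volume for flow, unit
peak for pressure) and warped/scaled to each patient.  Evaluation between
samples uses a monotone piecewise-cubic (PCHIP) interpolant so the ODE
right-hand side sees smooth values and analytic derivatives.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Waveform",
    "PatientRecord",
    "aortic_flow_template",
    "ventricular_pressure_template",
    "scale_inflow_waveform",
    "scale_pim_waveform",
    "stroke_volume_from_index",
    "read_waveform_csv",
    "write_waveform_csv",
]

MIN_SAMPLES_PER_PERIOD = 16


class Waveform:
    """A sampled periodic signal with smooth periodic evaluation.

    Parameters
    ----------
    times : array-like, seconds
        Strictly increasing sample times starting at 0, last time <= period.
    values : array-like
        Sample values (mL/s for flows, mmHg for pressures).
    period : float, seconds
        Cardiac cycle duration T. Evaluation is periodic: ``w(t) == w(t % T)``.
    """

    __slots__ = ("times", "values", "period", "_interp", "_dinterp")

    def __init__(self, times, values, period: float):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size < MIN_SAMPLES_PER_PERIOD:
            raise ValueError(
                f"waveform needs at least {MIN_SAMPLES_PER_PERIOD} samples per period"
            )
        if not np.isfinite(period) or period <= 0:
            raise ValueError("period must be positive and finite")
        if times[0] != 0.0:
            raise ValueError("waveform times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("waveform times must be strictly increasing")
        if times[-1] > period * (1 + 1e-12):
            raise ValueError("last sample time exceeds the period")
        self.times = times
        self.values = values
        self.period = float(period)
        # Close the cycle for the interpolant: wrap to the value at t=0 so
        # periodic evaluation is continuous across the cycle boundary.
        if times[-1] < period:
            ti = np.append(times, period)
            vi = np.append(values, values[0])
        else:
            ti, vi = times, values
        self._interp = PchipInterpolator(ti, vi, extrapolate=False)
        self._dinterp = self._interp.derivative()

    # -- evaluation ---------------------------------------------------------

    def _wrap(self, t):
        tm = np.mod(t, self.period)
        # clamp roundoff spill at the boundary
        return np.clip(tm, 0.0, self.period)

    def __call__(self, t):
        return self._interp(self._wrap(t))

    def derivative(self, t):
        """Analytic time derivative of the interpolant, periodic in t."""
        return self._dinterp(self._wrap(t))

    # -- summaries ----------------------------------------------------------

    def integral(self) -> float:
        """Integral of the interpolant over one full period."""
        return float(self._interp.antiderivative()(self.period))

    def mean(self) -> float:
        return self.integral() / self.period

    def max(self) -> float:
        # PCHIP is monotonicity-preserving: extrema occur at the samples.
        return float(self.values.max())

    def min(self) -> float:
        return float(self.values.min())

    def scaled(self, factor: float) -> "Waveform":
        return Waveform(self.times, self.values * factor, self.period)

    def __repr__(self):
        return (
            f"Waveform(n={self.times.size}, period={self.period:.4g} s, "
            f"range=[{self.values.min():.4g}, {self.values.max():.4g}])"
        )


@dataclass(frozen=True)
class PatientRecord:
    """Hemodynamic targets and anatomy scaling factors for one patient.

    artery_mass_fractions maps artery name (e.g. LAD/LCx/RCA/LM) to the
    fraction of left-ventricular myocardial mass it perfuses; fractions must
    sum to 1.
    """

    heart_rate: float  # beats/min
    systolic_pressure: float  # mmHg
    diastolic_pressure: float  # mmHg
    stroke_volume: float  # mL
    systolic_ejection_time: float  # s
    body_surface_area: float  # m^2
    myocardial_mass: float  # g
    artery_mass_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "heart_rate",
            "systolic_pressure",
            "diastolic_pressure",
            "stroke_volume",
            "systolic_ejection_time",
            "body_surface_area",
            "myocardial_mass",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.systolic_pressure <= self.diastolic_pressure:
            raise ValueError("systolic_pressure must exceed diastolic_pressure")
        total = sum(self.artery_mass_fractions.values())
        if self.artery_mass_fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"artery_mass_fractions must sum to 1 (got {total})")
        if any(f < 0 or f > 1 for f in self.artery_mass_fractions.values()):
            raise ValueError("artery_mass_fractions must lie in [0, 1]")
        object.__setattr__(
            self, "artery_mass_fractions", dict(self.artery_mass_fractions)
        )

    @property
    def period(self) -> float:
        """Cardiac cycle duration T in seconds."""
        return 60.0 / self.heart_rate

    @property
    def pulse_pressure(self) -> float:
        return self.systolic_pressure - self.diastolic_pressure

    @property
    def mean_arterial_pressure(self) -> float:
        """Diastolic + one third of pulse pressure (standard estimate)."""
        return self.diastolic_pressure + self.pulse_pressure / 3.0

    @property
    def cardiac_output(self) -> float:
        """mL/s."""
        return self.stroke_volume * self.heart_rate / 60.0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatientRecord":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PatientRecord":
        """Load from JSON or YAML with the canonical field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stroke_volume_from_index(stroke_volume_index: float, body_surface_area: float) -> float:
    """Absolute stroke volume (mL) from an indexed value (mL/m^2) and BSA (m^2)."""
    if stroke_volume_index <= 0 or body_surface_area <= 0:
        raise ValueError("stroke_volume_index and body_surface_area must be positive")
    return stroke_volume_index * body_surface_area


# ---------------------------------------------------------------------------
# Default templates
# ---------------------------------------------------------------------------


def aortic_flow_template(ejection_fraction: float = 0.35, n_ejection: int = 49,
                         n_diastole: int = 32) -> Waveform:
    """Normalized aortic flow shape: half-sine ejection, zero diastole.

    Unit period, unit (trapezoidal) stroke volume; the positive-flow window is
    exactly [0, ejection_fraction]. The ejection end is a sample point, so
    piecewise-linear time warping of the ejection window is exact.
    """
    if not 0 < ejection_fraction < 1:
        raise ValueError("ejection_fraction must lie in (0, 1)")
    te = np.linspace(0.0, ejection_fraction, n_ejection)
    ve = np.sin(np.pi * te / ejection_fraction)
    td = np.linspace(ejection_fraction, 1.0, n_diastole + 1)[1:]
    times = np.concatenate([te, td])
    values = np.concatenate([ve, np.zeros_like(td)])
    values = values / np.trapezoid(values, times)
    return Waveform(times, values, 1.0)


def ventricular_pressure_template(systole_fraction: float = 0.4, n_systole: int = 49,
                                  n_diastole: int = 32) -> Waveform:
    """Normalized ventricular-pressure shape: smooth systolic bump, peak 1.

    A raised-cosine (Hann) bump over [0, systole_fraction], zero in diastole,
    unit period. Stands in for population-averaged LV pressure shapes.
    """
    if not 0 < systole_fraction < 1:
        raise ValueError("systole_fraction must lie in (0, 1)")
    ts = np.linspace(0.0, systole_fraction, n_systole)
    vs = 0.5 * (1.0 - np.cos(2.0 * np.pi * ts / systole_fraction))
    td = np.linspace(systole_fraction, 1.0, n_diastole + 1)[1:]
    times = np.concatenate([ts, td])
    values = np.concatenate([vs, np.zeros_like(td)])
    return Waveform(times, values, 1.0)


# ---------------------------------------------------------------------------
# Patient scaling
# ---------------------------------------------------------------------------


def _active_window_end(template: Waveform, tol: float = 1e-12) -> float:
    """End of the template's leading nonzero window, normalized to unit period."""
    t = template.times / template.period
    nz = np.nonzero(np.abs(template.values) > tol)[0]
    if nz.size == 0:
        raise ValueError("template waveform is identically zero")
    last = nz[-1]
    # the window closes at the first zero sample after the active run (if any)
    return float(t[min(last + 1, t.size - 1)])


def _warp_times(t_norm: np.ndarray, window_end: float, new_window: float,
                new_period: float) -> np.ndarray:
    """Piecewise-linear warp of [0, window_end] -> [0, new_window] and
    [window_end, 1] -> [new_window, new_period]."""
    out = np.where(
        t_norm <= window_end,
        t_norm * (new_window / window_end),
        new_window + (t_norm - window_end) * (new_period - new_window) / (1.0 - window_end),
    )
    out[0] = 0.0
    return out


def scale_inflow_waveform(template: Waveform, patient: PatientRecord) -> Waveform:
    """Patient-specific aortic inflow from a normalized template.

    The template's ejection window is warped to the patient's systolic
    ejection time, the remainder to the diastolic interval, and values are
    scaled so the trapezoidal integral over one period equals the stroke
    volume. BSA scaling enters through the stroke volume (see
    :func:`stroke_volume_from_index`).
    """
    T = patient.period
    set_ = patient.systolic_ejection_time
    if set_ >= T:
        raise ValueError(
            f"systolic ejection time ({set_} s) must be shorter than the cycle ({T} s)"
        )
    t_norm = template.times / template.period
    window_end = _active_window_end(template)
    times = _warp_times(t_norm, window_end, set_, T)
    integral = np.trapezoid(template.values, times)
    if integral <= 0:
        raise ValueError("template inflow must carry positive net volume")
    values = template.values * (patient.stroke_volume / integral)
    return Waveform(times, values, T)


def scale_pim_waveform(template: Waveform, patient: PatientRecord,
                       territory_factor: float) -> Waveform:
    """Patient-specific intramyocardial pressure from a normalized template.

    The peak of the returned waveform equals ``territory_factor *
    systolic_pressure``; the systolic bump is warped to the patient's systolic
    ejection time and the period to the cardiac cycle. Amplitude-only scaling
    of the template shape (timing of the shape within systole is preserved).
    """
    if not 0.0 <= territory_factor <= 1.0:
        raise ValueError("territory_factor must lie in [0, 1]")
    T = patient.period
    set_ = patient.systolic_ejection_time
    if set_ >= T:
        raise ValueError("systolic ejection time must be shorter than the cycle")
    t_norm = template.times / template.period
    if territory_factor == 0.0:
        times = t_norm * T
        return Waveform(times, np.zeros_like(times), T)
    window_end = _active_window_end(template)
    times = _warp_times(t_norm, window_end, set_, T)
    peak = np.abs(template.values).max()
    values = template.values * (territory_factor * patient.systolic_pressure / peak)
    return Waveform(times, values, T)


# ---------------------------------------------------------------------------
# CSV I/O:  two columns `time_s,value`; optional `# period=...` comment line.
# ---------------------------------------------------------------------------


def read_waveform_csv(path) -> Waveform:
    path = Path(path)
    period = None
    times, values = [], []
    header_seen = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("period"):
                period = float(body.split("=", 1)[1])
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["time_s", "value"]:
                raise ValueError(
                    f"{path}: expected header 'time_s,value', got {line!r}"
                )
            header_seen = True
            continue
        a, b = line.split(",")[:2]
        times.append(float(a))
        values.append(float(b))
    if not header_seen:
        raise ValueError(f"{path}: missing 'time_s,value' header")
    if period is None:
        period = times[-1] if times else 0.0
    return Waveform(np.asarray(times), np.asarray(values), period)


def write_waveform_csv(waveform: Waveform, path) -> None:
    lines = [f"# period={waveform.period!r}", "time_s,value"]
    lines += [
        f"{float(t)!r},{float(v)!r}"
        for t, v in zip(waveform.times, waveform.values)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
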