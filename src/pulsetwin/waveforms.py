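"""Resampling, spectral and morphological analysis of pressure cycles.

A :class:`WaveformRecord` is one cardiac cycle at a named site.  The
toolkit provides periodic resampling to fixed length, harmonic energy
content, the 0.5 mmHg mean-absolute-error accuracy criterion used to
judge inverse reconstructions, morphological feature extraction
(systolic peak, dicrotic notch, pulse pressure) and foot-to-foot pulse
wave velocity with intersecting-tangent foot detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: fixed sequence length used by the learned models
DEFAULT_SAMPLES_PER_CYCLE = 200

#: a reconstruction is "accurate" below this cycle-averaged error
ACCURACY_THRESHOLD_MMHG = 0.5


@dataclass
class WaveformRecord:
    """One cardiac cycle of pressure (and optionally flow) at a site."""

    site: str
    time: np.ndarray                 # s, strictly increasing, spans one period
    pressure_mmhg: np.ndarray
    flow_ml_s: np.ndarray | None = None
    patient_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure_mmhg = np.asarray(self.pressure_mmhg, dtype=float)
        if self.time.ndim != 1 or self.time.size < 4:
            raise ValueError("waveform needs at least 4 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.pressure_mmhg.shape != self.time.shape:
            raise ValueError("time and pressure must have the same length")

    @property
    def period(self) -> float:
        # samples at 0, dt, ..., T-dt: the period closes one step past the end
        dt = self.time[1] - self.time[0]
        return float(self.time[-1] - self.time[0] + dt)


@dataclass
class ResampledCycle:
    """Fixed-length pressure sequence over one period."""

    pressure_mmhg: np.ndarray
    period: float
    site: str = ""
    patient_id: str = ""

    def __post_init__(self):
        self.pressure_mmhg = np.asarray(self.pressure_mmhg, dtype=float)

    @property
    def n(self) -> int:
        return self.pressure_mmhg.size

    @property
    def time(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.n, endpoint=False)


def resample_cycle(rec: WaveformRecord,
                   n: int = DEFAULT_SAMPLES_PER_CYCLE) -> ResampledCycle:
    """Periodic linear interpolation onto ``n`` uniform points in [0, T)."""
    if rec.time.size < 4:
        raise ValueError("need at least 4 source samples")
    T = rec.period
    t_src = rec.time - rec.time[0]
    # wrap the first sample to close the period
    t_ext = np.concatenate([t_src, [T]])
    p_ext = np.concatenate([rec.pressure_mmhg, [rec.pressure_mmhg[0]]])
    t_new = np.linspace(0.0, T, n, endpoint=False)
    p_new = np.interp(t_new, t_ext, p_ext)
    return ResampledCycle(pressure_mmhg=p_new, period=T,
                          site=rec.site, patient_id=rec.patient_id)


def harmonic_energy_fraction(cycle, k: int = 5) -> float:
    """Fraction of pulsatile spectral energy carried by harmonics 1..k.

    The mean (DC) component is excluded; by Parseval the fractions are
    ratios of summed squared Fourier magnitudes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(cycle.pressure_mmhg if hasattr(cycle, "pressure_mmhg")
                   else cycle, dtype=float)
    spec = np.fft.rfft(p - p.mean())
    energy = np.abs(spec) ** 2
    # double interior bins so the rfft energies satisfy Parseval
    weights = np.full(energy.size, 2.0)
    weights[0] = 1.0
    if p.size % 2 == 0:
        weights[-1] = 1.0
    energy = energy * weights
    total = energy[1:].sum()
    if total <= 0:
        raise ValueError("zero pulsatile energy: harmonic fraction undefined")
    kk = min(k, energy.size - 1)
    return float(energy[1:kk + 1].sum() / total)


def waveform_accuracy(predicted, expected,
                      threshold_mmhg: float = ACCURACY_THRESHOLD_MMHG):
    """Cycle-averaged absolute pressure error and the accuracy flag.

    A prediction is acceptable when the mean absolute pointwise error
    over the cardiac cycle is below ``threshold_mmhg``.
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(expected, dtype=float)
    if p.shape != e.shape:
        raise ValueError(f"cycle length mismatch: {p.shape} vs {e.shape}")
    err = float(np.mean(np.abs(p - e)))
    return err, err < threshold_mmhg


@dataclass
class CycleFeatures:
    t_peak: float
    p_peak: float
    p_min: float
    pulse_pressure: float
    t_notch: float | None = None
    p_notch: float | None = None
    notch_found: bool = False
    extras: dict = field(default_factory=dict)


def extract_features(cycle: ResampledCycle,
                     notch_window_frac: float = 0.4,
                     notch_rise_mmhg: float = 0.5) -> CycleFeatures:
    """Systolic peak, minimum, pulse pressure and dicrotic notch.

    The notch is the first local pressure minimum after the systolic
    peak (within ``notch_window_frac`` of the period) that is followed
    by a secondary rise of at least ``notch_rise_mmhg``.  Absence of a
    notch is flagged, not an error.
    """
    p = cycle.pressure_mmhg
    t = cycle.time
    if np.ptp(p) <= 0:
        raise ValueError("constant cycle has no morphology")
    i_peak = int(np.argmax(p))
    feats = CycleFeatures(
        t_peak=float(t[i_peak]), p_peak=float(p[i_peak]),
        p_min=float(np.min(p)),
        pulse_pressure=float(np.max(p) - np.min(p)))
    i_end = min(p.size - 2, i_peak + int(notch_window_frac * p.size))
    for i in range(i_peak + 1, i_end + 1):
        if p[i] <= p[i - 1] and p[i] < p[i + 1]:
            after = p[i:min(p.size, i + max(2, p.size // 10))]
            if np.max(after) - p[i] >= notch_rise_mmhg:
                feats.t_notch = float(t[i])
                feats.p_notch = float(p[i])
                feats.notch_found = True
                break
    return feats


def _foot_time(t: np.ndarray, p: np.ndarray) -> float:
    """Intersecting-tangent foot: max-upstroke tangent meets the
    diastolic minimum level."""
    dp = np.gradient(p, t)
    i_up = int(np.argmax(dp))          # steepest systolic upstroke
    slope = dp[i_up]
    if slope <= 0:
        raise ValueError("no rising edge found for foot detection")
    return float(t[i_up] - (p[i_up] - np.min(p)) / slope)


def heart_femoral_pwv(aortic_root_cycle, femoral_cycle,
                      path_length: float) -> float:
    """Foot-to-foot pulse wave velocity (m/s) over ``path_length`` (m)."""
    if path_length <= 0:
        raise ValueError("path length must be positive")
    ta = _foot_time(aortic_root_cycle.time, aortic_root_cycle.pressure_mmhg)
    tf = _foot_time(femoral_cycle.time, femoral_cycle.pressure_mmhg)
    T = getattr(femoral_cycle, "period", None) or (
        femoral_cycle.time[-1] - femoral_cycle.time[0])
    transit = (tf - ta) % T
    if transit <= 0 or transit > 0.5 * T:
        raise ValueError(f"non-physical transit time {transit:.4f} s")
    return path_length / transit
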