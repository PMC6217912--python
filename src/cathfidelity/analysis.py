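"""Measurement-derived waveform statistics.

Implements the analyses applied to the phantom pressure recordings:

* cycle features — peak systolic pressure P_s, diastolic minimum P_d,
  pulse pressure P_s - P_d, dicrotic-notch detection;
* the intersecting-tangents "foot" of the systolic upstroke and
  foot-to-foot pulse wave velocity over a probe array;
* zero-padded single-sided amplitude spectra and secondary-peak search;
* the curvature-sum quality statistic that screens for air-bubble
  distortion (published threshold 3.85: clean signals lie above it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.signal.windows import hann

from .errors import (DegenerateSignalError, DetectionError, DomainError,
                     ParameterError)
from .waveforms import PressureWaveform

__all__ = [
    "WaveFeatures",
    "PWVResult",
    "SpectrumResult",
    "CurvatureQC",
    "SpectralPeak",
    "CURVATURE_THRESHOLD",
    "select_cycle",
    "extract_features",
    "detect_foot",
    "pwv_foot_to_foot",
    "amplitude_spectrum",
    "secondary_peak",
    "dicrotic_ring_spectrum",
    "curvature_sum",
]

CURVATURE_THRESHOLD = 3.85
"""Published curvature-sum threshold separating distorted traces from controls."""

# Minimum rebound (mmHg) for a diastolic local-min/local-max pair to count
# as a dicrotic notch rather than numerical ripple.
NOTCH_MIN_REBOUND = 0.1


@dataclass(frozen=True)
class WaveFeatures:
    """Per-record pressure features (cycle-averaged where applicable)."""

    P_s: float                    # peak systolic pressure (mmHg)
    P_d: float                    # diastolic minimum (mmHg)
    notch_present: bool
    notch_time: float | None      # s, within the designated cycle
    foot_times: tuple[float, ...]  # upstroke foot per analyzed cycle (s)

    @property
    def pulse_pressure(self) -> float:
        """P_s - P_d (mmHg)."""
        return self.P_s - self.P_d


@dataclass(frozen=True)
class PWVResult:
    """Foot-to-foot pulse wave velocity over one probe separation."""

    dx: float                                     # separation (m)
    pairs: tuple[tuple[float, float, float], ...]  # (x_up, x_down, transit time s)
    pwv: float                                    # m/s
    method: str = "mean_of_ratios"


@dataclass(frozen=True)
class SpectrumResult:
    """Zero-padded single-sided amplitude spectrum."""

    freqs: np.ndarray       # Hz, ascending from 0
    amps: np.ndarray        # single-sided amplitudes (mmHg)
    pad_factor: int
    fundamental: float      # frequency of the global (non-DC) maximum (Hz)
    parseval_ratio: float   # spectral energy / signal energy (== 1 by Parseval)


class SpectralPeak(NamedTuple):
    """A located spectral peak (frequency in Hz, single-sided amplitude in mmHg)."""

    freq: float
    amp: float


@dataclass(frozen=True)
class CurvatureQC:
    """Curvature-sum air-bubble screen."""

    curvature_sum: float
    threshold: float = CURVATURE_THRESHOLD
    distorted: bool = field(init=False)

    def __post_init__(self):
        if not (np.isfinite(self.curvature_sum) and self.curvature_sum >= 0):
            raise ParameterError("curvature_sum: must be finite and >= 0")
        # clean reference signals lie above the threshold; a low curvature
        # sum indicates an over-smoothed (bubble-distorted) trace
        object.__setattr__(self, "distorted", self.curvature_sum < self.threshold)


def _n_cycle(w: PressureWaveform, cycle_period: float) -> int:
    if not (np.isfinite(cycle_period) and cycle_period > 0):
        raise ParameterError("cycle_period: must be > 0")
    n_cyc = int(round(cycle_period * w.rate))
    if n_cyc < 4 or n_cyc > w.samples.size:
        raise ParameterError(
            "cycle_period: record must span at least one full cycle")
    return n_cyc


def select_cycle(w: PressureWaveform, cycle_period: float,
                 index: int = -1) -> PressureWaveform:
    """Extract one complete cycle (default: the last complete one)."""
    n_cyc = _n_cycle(w, cycle_period)
    n_full = w.samples.size // n_cyc
    if n_full < 1:
        raise ParameterError("cycle_period: record shorter than one cycle")
    idx = range(n_full)[index]
    s = idx * n_cyc
    return PressureWaveform(w.samples[s:s + n_cyc], w.rate,
                            w.t0 + s / w.rate)


def _smooth(y: np.ndarray, rate: float) -> np.ndarray:
    """Light Savitzky-Golay smoothing (~50 ms window, cubic) for extrema search."""
    win = int(round(0.05 * rate))
    win = max(5, win + (win + 1) % 2)  # odd, >= 5
    if y.size <= win:
        return y
    return savgol_filter(y, win, 3)


def extract_features(w: PressureWaveform, cycle_period: float,
                     transient: float = 0.0) -> WaveFeatures:
    """Cycle features of a pressure record.

    P_s and P_d are the max/min over complete cycles (samples inside the
    leading ``transient`` seconds are excluded, e.g. the settling time of a
    simulated transducer). The dicrotic notch is sought on the designated
    (last complete) cycle as the first local-minimum / local-maximum pair
    after the systolic peak on the lightly smoothed curve, requiring a
    rebound of at least 0.1 mmHg.
    """
    n_cyc = _n_cycle(w, cycle_period)
    i0 = int(math.ceil(transient * w.rate))
    n_full = (w.samples.size - i0) // n_cyc
    if n_full < 1:
        raise ParameterError("record holds no complete cycle after the transient")
    body = w.samples[i0:i0 + n_full * n_cyc]
    P_s = float(np.max(body))
    P_d = float(np.min(body))

    cyc = select_cycle(
        PressureWaveform(body, w.rate, w.t0 + i0 / w.rate), cycle_period, -1)
    ys = _smooth(cyc.samples, w.rate)
    ipk = int(np.argmax(ys))
    notch_present = False
    notch_time = None
    i = ipk + 1
    while i < ys.size - 1:
        if ys[i] < ys[i - 1] and ys[i] <= ys[i + 1]:       # local minimum
            j = i + 1
            while j < ys.size - 1 and ys[j] <= ys[j - 1]:
                j += 1
            while j < ys.size - 1 and ys[j + 1] >= ys[j]:
                j += 1
            if j < ys.size and ys[j] - ys[i] >= NOTCH_MIN_REBOUND:
                notch_present = True
                notch_time = float(cyc.t0 + i / w.rate)
                break
            i = j
        i += 1

    feet = []
    for c in range(n_full):
        start = w.t0 + (i0 + c * n_cyc) / w.rate
        try:
            feet.append(detect_foot(w, start, cycle_period))
        except DetectionError:
            if P_s > P_d:
                raise
    return WaveFeatures(P_s=P_s, P_d=P_d, notch_present=notch_present,
                        notch_time=notch_time, foot_times=tuple(feet))


def detect_foot(w: PressureWaveform, cycle_start: float,
                cycle_period: float | None = None) -> float:
    """Intersecting-tangents foot of the systolic upstroke (seconds).

    Within the window starting at ``cycle_start`` (one period long if
    ``cycle_period`` is given, else the rest of the record), the foot is
    the intersection of the horizontal line through the pre-upstroke
    minimum with the tangent at the point of steepest rise. The steepest
    point and its slope are refined to sub-sample resolution by a local
    quadratic fit to the first derivative.
    """
    i_start = int(round((cycle_start - w.t0) * w.rate))
    i_start = max(0, i_start)
    if cycle_period is not None:
        i_end = min(w.samples.size, i_start + int(round(cycle_period * w.rate)) + 1)
    else:
        i_end = w.samples.size
    y = w.samples[i_start:i_end]
    if y.size < 5:
        raise DetectionError("window too short to locate an upstroke")
    if np.ptp(y) <= 0:
        raise DetectionError("flat window: no systolic upstroke")

    # the systolic upstroke is the rise toward the window's global maximum;
    # restrict the slope search there so later (reflected) fronts are ignored
    ipk = int(np.argmax(y))
    d = np.gradient(y) * w.rate
    im = int(np.argmax(d[:ipk + 1])) if ipk > 0 else int(np.argmax(d))
    if d[im] <= 0:
        raise DetectionError("no rising limb in the window")

    # sub-sample refinement: quadratic through the derivative at im-1, im, im+1
    if 0 < im < y.size - 1:
        dm, d0, dp = d[im - 1], d[im], d[im + 1]
        denom = dm - 2 * d0 + dp
        delta = 0.0 if denom == 0 else 0.5 * (dm - dp) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        slope = d0 - 0.25 * (dm - dp) * delta
    else:
        delta, slope = 0.0, d[im]
    t_m = (i_start + im + delta) / w.rate + w.t0
    p_m = float(np.interp(i_start + im + delta,
                          np.arange(w.samples.size), w.samples))

    baseline = float(np.min(y[:im + 1]))
    if slope <= 0:
        raise DetectionError("non-positive upstroke slope")
    return t_m - (p_m - baseline) / slope


def pwv_foot_to_foot(probes: Sequence[tuple[float, PressureWaveform]],
                     dx: float, cycle_start: float | None = None,
                     cycle_period: float | None = None,
                     method: str = "mean_of_ratios",
                     position_tol: float = 1e-6) -> PWVResult:
    """Foot-to-foot pulse wave velocity over all probe pairs separated by ``dx``.

    For every ordered pair of probes whose separation matches ``dx`` the
    transit time is (downstream foot - upstream foot); the PWV is the mean
    of dx/dt over the pairs (``method="mean_of_ratios"``, default) or
    dx / mean(dt) (``method="ratio_of_means"``). A non-positive transit
    time signals reflection-contaminated feet and is an error.
    """
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ParameterError("method: mean_of_ratios or ratio_of_means")
    if not (np.isfinite(dx) and dx > 0):
        raise ParameterError("dx: must be > 0")
    probes = sorted(probes, key=lambda p: p[0])
    feet = {}
    for xpos, wf in probes:
        start = wf.t0 if cycle_start is None else cycle_start
        feet[xpos] = detect_foot(wf, start, cycle_period)
    pairs = []
    for i, (x_up, _) in enumerate(probes):
        for x_dn, _ in probes[i + 1:]:
            if abs((x_dn - x_up) - dx) <= position_tol:
                dt_pair = feet[x_dn] - feet[x_up]
                if dt_pair <= 0:
                    raise DetectionError(
                        f"non-positive transit time between x={x_up} and x={x_dn}; "
                        "feet likely reflection-contaminated")
                pairs.append((x_up, x_dn, dt_pair))
    if not pairs:
        raise DetectionError(f"no probe pair at separation dx={dx}")
    if method == "mean_of_ratios":
        pwv = float(np.mean([dx / p[2] for p in pairs]))
    else:
        pwv = dx / float(np.mean([p[2] for p in pairs]))
    return PWVResult(dx=dx, pairs=tuple(pairs), pwv=pwv, method=method)


def amplitude_spectrum(w: PressureWaveform, pad_factor: int = 8,
                       window: str | None = None) -> SpectrumResult:
    """Zero-padded single-sided amplitude spectrum of a (detrended) record.

    The mean is removed, an optional taper applied (``window="hann"``), and
    the signal zero-padded to ``pad_factor`` times its length before the
    FFT; amplitudes are normalized by the window's coherent gain so a
    full-scale sinusoid of amplitude a reports a. ``parseval_ratio`` stores
    the ratio of spectral to time-domain energy of the windowed signal
    (identically 1 up to rounding).
    """
    if int(pad_factor) != pad_factor or pad_factor < 1:
        raise ParameterError("pad_factor: must be an integer >= 1")
    y = w.samples - np.mean(w.samples)
    n = y.size
    if window is None:
        win = np.ones(n)
    elif window == "hann":
        win = hann(n)
    else:
        raise ParameterError(f"window: unknown taper {window!r}")
    yw = y * win
    n_fft = int(n * pad_factor)
    X = np.fft.rfft(yw, n_fft)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / w.rate)
    amps = 2.0 * np.abs(X) / np.sum(win)
    amps[0] /= 2.0
    if n_fft % 2 == 0:
        amps[-1] /= 2.0

    energy_sig = float(np.sum(yw ** 2))
    # two-sided Parseval: sum|X_k|^2 over the full DFT / n_fft == sum x^2
    two_sided = np.abs(X) ** 2
    energy_spec = (2.0 * np.sum(two_sided) - two_sided[0]
                   - (two_sided[-1] if n_fft % 2 == 0 else 0.0)) / n_fft
    ratio = 1.0 if energy_sig == 0 else energy_spec / energy_sig

    i_fund = 1 + int(np.argmax(amps[1:]))
    return SpectrumResult(freqs=freqs, amps=amps, pad_factor=int(pad_factor),
                          fundamental=float(freqs[i_fund]),
                          parseval_ratio=float(ratio))


def secondary_peak(s: SpectrumResult, exclusion_band: float = 3.0,
                   floor_frac: float = 0.01) -> SpectralPeak | None:
    """Largest local spectral maximum above the fundamental's exclusion band.

    Returns the peak frequency/amplitude, or None if no local maximum above
    ``exclusion_band`` Hz reaches ``floor_frac`` times the fundamental's
    amplitude. Absence is a valid result (a fully damped record).
    """
    if not (np.isfinite(exclusion_band) and exclusion_band >= 0):
        raise ParameterError("exclusion_band: must be >= 0")
    a, f = s.amps, s.freqs
    i_fund = int(np.argmin(np.abs(f - s.fundamental)))
    floor = floor_frac * a[i_fund]
    interior = (f[1:-1] > exclusion_band)
    is_max = (a[1:-1] >= a[:-2]) & (a[1:-1] > a[2:]) & (a[1:-1] >= floor)
    idx = np.nonzero(interior & is_max)[0] + 1
    if idx.size == 0:
        return None
    best = idx[np.argmax(a[idx])]
    return SpectralPeak(freq=float(f[best]), amp=float(a[best]))


def dicrotic_ring_spectrum(w: PressureWaveform, cycle_period: float,
                           pad_factor: int = 32,
                           cycle_index: int = -1) -> SpectrumResult | None:
    """Spectrum of the dicrotic oscillation of one designated cycle.

    An exactly periodic record carries spectral lines only at multiples of
    the heart rate, so an inter-harmonic ring mode is invisible to the
    full-record transform. This estimator therefore isolates the ring: it
    takes the designated cycle's descending limb from the dicrotic dip
    onward, removes the exponential diastolic trend, tapers (Hann) and
    zero-pads. Feeding the result to :func:`secondary_peak` recovers the
    ring frequency. Returns None when no post-systolic dip exists (no
    visible oscillation).
    """
    cyc = select_cycle(w, cycle_period, cycle_index)
    y = cyc.samples
    ipk = int(np.argmax(_smooth(y, w.rate)))
    i_dip = None
    for i in range(ipk + 1, y.size - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            i_dip = i
            break
    if i_dip is None or y.size - i_dip < 8:
        return None
    seg = y[i_dip:].astype(float)
    x = np.arange(seg.size) / w.rate

    def expdec(t, a, b, c):
        return a * np.exp(-b * t) + c

    try:
        coef, _ = curve_fit(expdec, x, seg,
                            p0=(max(seg[0] - seg[-1], 1e-6), 2.0, seg[-1]),
                            bounds=((-np.inf, 0.0, -np.inf),
                                    (np.inf, 200.0, np.inf)),
                            maxfev=5000)
        resid = seg - expdec(x, *coef)
    except RuntimeError:
        # fall back to a cubic trend if the exponential fit fails
        c3 = np.polynomial.polynomial.polyfit(x, seg, 3)
        resid = seg - np.polynomial.polynomial.polyval(x, c3)

    seg_w = PressureWaveform(resid + np.mean(seg), w.rate, cyc.t0 + i_dip / w.rate)
    return amplitude_spectrum(seg_w, pad_factor=pad_factor, window="hann")


def curvature_sum(w: PressureWaveform, cycle_period: float | None = None) -> CurvatureQC:
    """Curvature-sum quality statistic of a pressure record.

    Each complete cycle (the whole record if ``cycle_period`` is None) is
    normalized to the unit square (time and amplitude each rescaled to
    [0, 1]); the geometric curvature kappa = |y''| / (1 + y'^2)^(3/2) is
    evaluated by central differences on the normalized curve and integrated
    over the cycle (sum x step). Multi-cycle records report the per-cycle
    average. Heavily smoothed (air-bubble-distorted) traces lose curvature
    and fall below the 3.85 threshold.
    """
    if cycle_period is None:
        cycles = [w.samples]
    else:
        n_cyc = _n_cycle(w, cycle_period)
        n_full = w.samples.size // n_cyc
        cycles = [w.samples[c * n_cyc:(c + 1) * n_cyc] for c in range(n_full)]
    sums = []
    for y in cycles:
        span = np.ptp(y)
        if span <= 0:
            raise DegenerateSignalError(
                "constant cycle: curvature normalization undefined")
        yn = (y - np.min(y)) / span
        dx = 1.0 / (y.size - 1)
        yp = np.gradient(yn, dx)
        ypp = np.gradient(yp, dx)
        kappa = np.abs(ypp) / (1.0 + yp ** 2) ** 1.5
        sums.append(float(np.sum(kappa) * dx))
    return CurvatureQC(curvature_sum=float(np.mean(sums)))
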