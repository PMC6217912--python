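"""Synthetic pressure and flow waveform generation.

The generator emulates the operating point of a pulsatile flow phantom
driven at 60 beats/min: a smooth systolic upstroke to a physiological peak,
a deliberately low end-diastolic pressure, and a damped oscillation on the
descending limb that produces the dicrotic notch and a secondary spectral
mode near 5.4 Hz.

The pressure cycle is piecewise analytic so that every clinically relevant
feature maps onto exactly one parameter:

* systolic upstroke: ``sin^2`` ramp from ``p_dia`` to ``p_sys``;
* systolic downstroke: ``cos^2`` fall from ``p_sys`` to an end-systolic
  shoulder;
* diastole: exponential run-off pinned to reach ``p_dia`` exactly at end of
  cycle;
* dicrotic ring: exponentially damped sinusoid at ``ring_freq`` starting at
  end-systole, tapered (``cos^2``) to zero at the cycle end so the tiled
  record stays continuous.

The cycle is tiled periodically, so the noiseless record is exactly
periodic by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

__all__ = [
    "PressureWaveform",
    "FlowWaveform",
    "WaveformParams",
    "generate_pressure_waveform",
    "generate_inlet_flow",
    "add_bubble_distortion",
    "add_noise",
]

# Shape constants of the analytic cycle, as fractions of the cycle period.
# Chosen to mimic a 60 bpm phantom pulse: ~0.25 s time-to-peak, ~0.42 s
# ejection, diastolic time constant ~0.35 s.
FRAC_PEAK = 0.25      # time of systolic peak / period
FRAC_END_SYSTOLE = 0.42  # start of diastolic run-off (and of the ring)
SHOULDER_FRAC = 0.35  # end-systolic pressure above p_dia, as fraction of pulse pressure
TAU_FRAC = 0.35       # diastolic exponential time constant / period


def _as_samples(samples, name: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ParameterError(f"{name}: need a 1-D array of at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name}: samples must all be finite")
    return arr


@dataclass(frozen=True)
class PressureWaveform:
    """A uniformly sampled pressure time series.

    Parameters
    ----------
    samples : array of float
        Pressure values in mmHg.
    rate : float
        Sampling frequency in Hz. Sample ``i`` is at time ``t0 + i / rate``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_samples(self.samples, "samples"))
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ParameterError("rate: must be finite and > 0")
        if not np.isfinite(self.t0):
            raise ParameterError("t0: must be finite")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        """Record duration (first to last sample) in seconds."""
        return (self.samples.size - 1) / self.rate

    def with_samples(self, samples) -> "PressureWaveform":
        """Copy of this waveform with new sample values (same rate and t0)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class FlowWaveform:
    """A uniformly sampled volumetric flow time series (m^3/s).

    Structurally identical to :class:`PressureWaveform`; the periodic
    extension over the cycle must be continuous (first ~ last sample).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_samples(self.samples, "samples"))
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ParameterError("rate: must be finite and > 0")
        if not np.isfinite(self.t0):
            raise ParameterError("t0: must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the synthetic pressure generator.

    Defaults mirror the phantom operating point: 60 beats/min, peak systolic
    pressure 106.4 mmHg, end-diastolic pressure 5.54 mmHg (deliberately low,
    a constraint of the phantom's venous return), a 5.4 Hz dicrotic ring,
    100 Hz sampling.
    """

    heart_rate: float = 60.0      # beats/min
    p_sys: float = 106.4          # mmHg
    p_dia: float = 5.54           # mmHg
    ring_freq: float = 5.4        # Hz
    ring_decay: float = 3.0       # 1/s
    ring_amp: float = 6.0         # mmHg
    n_cycles: int = 10
    rate: float = 100.0           # Hz
    seed: int = 0                 # RNG seed for optional noise paths

    def __post_init__(self):
        for name in ("heart_rate", "p_sys", "p_dia", "ring_freq",
                     "ring_decay", "ring_amp", "rate"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name}: must be finite")
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate: must be > 0")
        if self.p_sys < self.p_dia:
            raise ParameterError("p_sys: must be >= p_dia")
        if self.ring_freq <= self.heart_rate / 60.0:
            raise ParameterError("ring_freq: must exceed the fundamental (heart_rate/60)")
        if self.ring_decay < 0:
            raise ParameterError("ring_decay: must be >= 0")
        if self.ring_amp < 0:
            raise ParameterError("ring_amp: must be >= 0")
        if int(self.n_cycles) != self.n_cycles or self.n_cycles < 1:
            raise ParameterError("n_cycles: must be an integer >= 1")
        if self.rate <= 0:
            raise ParameterError("rate: must be > 0")

    @property
    def period(self) -> float:
        """Cycle period in seconds."""
        return 60.0 / self.heart_rate


def _cycle_pressure(phase: np.ndarray, params: WaveformParams) -> np.ndarray:
    """Evaluate the analytic cycle at phase times ``phase`` in [0, T)."""
    T = params.period
    pp = params.p_sys - params.p_dia
    t1 = FRAC_PEAK * T
    t2 = FRAC_END_SYSTOLE * T
    tau = TAU_FRAC * T
    p_es = params.p_dia + SHOULDER_FRAC * pp

    p = np.empty_like(phase)
    m1 = phase < t1
    p[m1] = params.p_dia + pp * np.sin(0.5 * np.pi * phase[m1] / t1) ** 2
    m2 = (phase >= t1) & (phase < t2)
    p[m2] = p_es + (params.p_sys - p_es) * np.cos(
        0.5 * np.pi * (phase[m2] - t1) / (t2 - t1)) ** 2
    m3 = phase >= t2
    decay_norm = math.exp(-(T - t2) / tau)
    p[m3] = params.p_dia + (p_es - params.p_dia) * (
        np.exp(-(phase[m3] - t2) / tau) - decay_norm) / (1.0 - decay_norm)

    if params.ring_amp > 0:
        tp = phase[m3] - t2
        env = np.exp(-params.ring_decay * tp) * np.cos(
            0.5 * np.pi * tp / (T - t2)) ** 2
        # leading minus: the ring first dips (notch) then rebounds
        p[m3] -= params.ring_amp * env * np.sin(2 * np.pi * params.ring_freq * tp)
    return p


def generate_pressure_waveform(params: WaveformParams) -> PressureWaveform:
    """Generate ``params.n_cycles`` of the analytic pressure cycle.

    The returned record is noiseless and exactly periodic; ``max(samples)``
    equals ``p_sys`` and ``min(samples)`` equals ``p_dia`` (each within
    0.5 mmHg as long as the ring amplitude is small relative to the pulse
    pressure).
    """
    T = params.period
    n_total = int(round(params.n_cycles * T * params.rate))
    if n_total < 2:
        raise ParameterError("rate: too low to resolve the requested cycles")
    t = np.arange(n_total) / params.rate
    phase = np.mod(t, T)
    return PressureWaveform(_cycle_pressure(phase, params), params.rate, 0.0)


def generate_inlet_flow(heart_rate: float, mean_velocity: float,
                        lumen_radius: float, n_cycles: int = 4,
                        rate: float = 1000.0,
                        ejection_frac: float = 0.3,
                        rise_frac: float = 0.2) -> FlowWaveform:
    """Pulsatile inlet flow: an asymmetric systolic ejection pulse, zero diastolic flow.

    The ejection occupies the first ``ejection_frac`` of the cycle; within
    it the flow accelerates over ``rise_frac`` of the ejection window
    (``sin^2`` ramp, so the onset is fast, as aortic flow is) and decays
    over the remainder (``cos^2`` fall). The pulse height is scaled so that
    the discrete cycle-mean flow equals
    ``mean_velocity * pi * lumen_radius**2`` exactly.

    Parameters are in SI units (m/s, m, Hz); flow is returned in m^3/s.
    """
    if not (np.isfinite(heart_rate) and heart_rate > 0):
        raise ParameterError("heart_rate: must be > 0")
    if not (np.isfinite(mean_velocity) and mean_velocity >= 0):
        raise ParameterError("mean_velocity: must be >= 0")
    if not (np.isfinite(lumen_radius) and lumen_radius > 0):
        raise ParameterError("lumen_radius: must be > 0")
    if int(n_cycles) != n_cycles or n_cycles < 1:
        raise ParameterError("n_cycles: must be an integer >= 1")
    if not (np.isfinite(rate) and rate > 0):
        raise ParameterError("rate: must be > 0")
    if not (0 < ejection_frac <= 1):
        raise ParameterError("ejection_frac: must be in (0, 1]")
    if not (0 < rise_frac < 1):
        raise ParameterError("rise_frac: must be in (0, 1)")

    T = 60.0 / heart_rate
    n_cycle = int(round(T * rate))
    n_ej = max(4, int(round(ejection_frac * n_cycle)))
    n_rise = max(2, int(round(rise_frac * n_ej)))
    q_mean = mean_velocity * math.pi * lumen_radius ** 2
    shape = np.zeros(n_cycle)
    k_up = np.arange(n_rise)
    shape[:n_rise] = np.sin(0.5 * np.pi * k_up / n_rise) ** 2
    k_dn = np.arange(n_ej - n_rise)
    shape[n_rise:n_ej] = np.cos(0.5 * np.pi * k_dn / (n_ej - n_rise)) ** 2
    shape_mean = float(np.mean(shape))
    q_peak = 0.0 if shape_mean == 0 else q_mean / shape_mean
    cycle = q_peak * shape
    return FlowWaveform(np.tile(cycle, int(n_cycles)), rate, 0.0)


def add_bubble_distortion(w: PressureWaveform, degraded_fn: float,
                          degraded_zeta: float) -> PressureWaveform:
    """Distort a waveform through a degraded (air-bubble-like) transducer response.

    Air bubbles in the lumen lower the natural frequency and raise the
    damping of the catheter-manometer system; the distortion is the same
    second-order low-pass model used for the nominal catheter, just with
    degraded parameters. Delegates to
    :func:`cathfidelity.transducer.measure_with_catheter`.
    """
    from .transducer import measure_with_catheter

    return measure_with_catheter(w, degraded_fn, degraded_zeta)


def add_noise(w: PressureWaveform, sd: float, seed: int) -> PressureWaveform:
    """Add zero-mean Gaussian measurement noise (mmHg); reproducible for a fixed seed."""
    if not (np.isfinite(sd) and sd >= 0):
        raise ParameterError("sd: must be >= 0")
    if sd == 0:
        return w
    rng = np.random.default_rng(seed)
    return w.with_samples(w.samples + rng.normal(0.0, sd, w.samples.size))
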