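"""Inlet flow programs and derived flow quantities for a two-inlet microchannel.

A Y-shaped microchannel receives an ATP-laden stream at a constant flow rate
``Q1`` (inlet 1) and a perfusion stream at a programmable, possibly pulsatile
flow rate ``Q2(t)`` (inlet 2).  Because the flow is laminar and inertia-free,
the two co-flowing streams occupy widths proportional to their flow rates, so
the ATP stream fills the fraction

    eps(t) = Q1 / (Q1 + Q2(t))

of the channel width at every instant.  The total flow rate Q(t) = Q1 + Q2(t)
sets the mean axial velocity and, through the plane-Poiseuille profile, the
wall shear stress

    tau_w(t) = 6 * eta * Q(t) / (W * H**2)

felt by cells cultured on the channel floor.  This module defines the flow
programs (steady, sinusoidal, or arbitrary sampled waveforms), these derived
quantities, and generic time-series metrics (mean, peak-to-peak, dominant
frequency, first-peak time) used to characterise emerging signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import signal as _sig

__all__ = [
    "ChannelGeometry",
    "SteadyFlow",
    "SinusoidalFlow",
    "SampledFlow",
    "FlowProgram",
    "TimeSeries",
    "SignalMetrics",
    "WaveformDomainError",
    "DegenerateFlowError",
    "total_flow",
    "flow_fraction",
    "wall_shear_stress",
    "signal_metrics",
]


class WaveformDomainError(ValueError):
    """A sampled waveform was queried outside its time span."""


class DegenerateFlowError(ValueError):
    """Both inlet flow rates are zero, so the stream fraction is undefined."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Main-channel dimensions (metres).

    Defaults are the reference chip: a 1 cm long channel of height 1 mm and
    width 50 um.
    """

    length: float = 1e-2
    height: float = 1e-3
    width: float = 5e-5

    def __post_init__(self) -> None:
        for name in ("length", "height", "width"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"ChannelGeometry.{name} must be positive, got {v!r}")

    @classmethod
    def reference_shallow(cls) -> "ChannelGeometry":
        """Shallow variant of the reference chip (height 50 um, width 1 mm).

        This is the wide, shallow Hele-Shaw-like cross-section that reproduces
        the reference chip's measured fill-in time (~4 s) and outlet ATP levels,
        and gives physiological wall shear (~0.7 Pa) at the nominal flow rates;
        the nominal (default) assignment yields a deep slot with ~20x weaker
        shear. Used by the shipped chip-protocol configuration.
        """
        return cls(length=1e-2, height=5e-5, width=1e-3)


@dataclass(frozen=True)
class SteadyFlow:
    """Constant flow rate (m^3/s)."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("flow rate must be nonnegative")

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value)

    def max_rate(self, t_end: float) -> float:
        return self.value

    def min_period(self) -> Optional[float]:
        return None


@dataclass(frozen=True)
class SinusoidalFlow:
    """Pulsatile flow  Q(t) = mean * (1 + delta * sin(2*pi*f*t + phase)).

    ``delta`` is the pulsatile amplitude fraction; ``delta <= 1`` keeps the
    rate nonnegative.
    """

    mean: float
    amplitude_fraction: float
    frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("mean flow rate must be nonnegative")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise ValueError(
                "amplitude_fraction must be in [0, 1] so Q(t) stays nonnegative"
            )
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.mean * (
            1.0
            + self.amplitude_fraction
            * np.sin(2.0 * np.pi * self.frequency * t + self.phase)
        )

    def max_rate(self, t_end: float) -> float:
        return self.mean * (1.0 + self.amplitude_fraction)

    def min_period(self) -> Optional[float]:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class SampledFlow:
    """Arbitrary waveform given as samples, linearly interpolated.

    Queries outside ``[times[0], times[-1]]`` raise
    :class:`WaveformDomainError`; a replayed pump waveform has no meaning
    beyond its recorded span.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ValueError("times and values must be 1-D arrays of equal length >= 2")
        if not np.all(np.diff(times) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("flow rates must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise WaveformDomainError(
                f"time outside sampled span [{self.times[0]}, {self.times[-1]}]"
            )
        return np.interp(t, self.times, self.values)

    def max_rate(self, t_end: float) -> float:
        return float(self.values.max())

    def min_period(self) -> Optional[float]:
        # Shortest feature a sampled waveform can encode.
        return 2.0 * float(np.min(np.diff(self.times)))


Waveform = Union[SteadyFlow, SinusoidalFlow, SampledFlow]


@dataclass(frozen=True)
class FlowProgram:
    """Pairing of the constant ATP-stream rate ``q1`` with the perfusion
    waveform ``q2``."""

    q1: float
    q2: Waveform

    def __post_init__(self) -> None:
        if self.q1 < 0:
            raise ValueError("q1 must be nonnegative")

    def total(self, t):
        """Total flow rate Q(t) = Q1 + Q2(t) (m^3/s)."""
        return self.q1 + self.q2(t)

    def fraction(self, t):
        """ATP-stream width fraction eps(t) = Q1 / (Q1 + Q2(t))."""
        q = self.total(t)
        if np.any(np.asarray(q) <= 0):
            raise DegenerateFlowError("Q1 + Q2(t) must be positive to define eps(t)")
        return self.q1 / q

    def max_total(self, t_end: float) -> float:
        return self.q1 + self.q2.max_rate(t_end)


def total_flow(program: FlowProgram, t):
    """Total flow rate Q(t) = Q1 + Q2(t) (m^3/s)."""
    return program.total(t)


def flow_fraction(program: FlowProgram, t):
    """ATP-stream width fraction eps(t) in [0, 1]."""
    return program.fraction(t)


def wall_shear_stress(program: FlowProgram, geometry: ChannelGeometry, viscosity: float, t):
    """Wall shear stress tau_w(t) = 6*eta*Q(t)/(W*H^2) on the channel floor (Pa)."""
    return (
        6.0
        * viscosity
        * program.total(t)
        / (geometry.width * geometry.height**2)
    )


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled time series."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("t and v must be 1-D arrays of equal length >= 2")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("t must be uniformly sampled")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path, value_name: str = "value", value_units: str = "") -> None:
        header = f"t_s,{value_name}" + (f"_{value_units}" if value_units else "")
        np.savetxt(path, np.column_stack([self.t, self.v]), delimiter=",",
                   header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(t=data[:, 0], v=data[:, 1])


@dataclass(frozen=True)
class SignalMetrics:
    mean: float
    peak_to_peak: float
    dominant_frequency: Optional[float]
    first_peak_time: Optional[float]


def signal_metrics(
    series: TimeSeries,
    transient_fraction: float = 0.25,
    prominence_fraction: float = 0.1,
) -> SignalMetrics:
    """Summary metrics of a uniformly sampled signal.

    ``mean``, ``peak_to_peak`` and ``dominant_frequency`` are computed on the
    analysis window that excludes the leading ``transient_fraction`` of the
    record (signals here typically carry a fill-in transient before settling
    into periodic behaviour).  ``dominant_frequency`` is the frequency of the
    largest nonzero-frequency periodogram component of the mean-removed
    window, or ``None`` for a (numerically) constant signal.
    ``first_peak_time`` is the time of the first local maximum of the *whole*
    record whose prominence exceeds ``prominence_fraction`` of the global
    range — the onset transient is exactly what it is meant to locate.
    """
    n = series.t.size
    start = int(np.floor(transient_fraction * n))
    start = min(max(start, 0), n - 2)
    tw = series.t[start:]
    vw = series.v[start:]

    mean = float(np.mean(vw))
    p2p = float(np.max(vw) - np.min(vw))

    vrange = float(np.max(series.v) - np.min(series.v))
    dom: Optional[float] = None
    if vrange > 0 and p2p > 1e-12 * max(1.0, abs(mean)):
        detrended = vw - np.mean(vw)
        freqs, power = _sig.periodogram(detrended, fs=1.0 / series.dt)
        if freqs.size > 1:
            k = 1 + int(np.argmax(power[1:]))
            if power[k] > 0:
                dom = float(freqs[k])

    first_peak: Optional[float] = None
    if vrange > 0:
        peaks, _ = _sig.find_peaks(series.v, prominence=prominence_fraction * vrange)
        if peaks.size:
            first_peak = float(series.t[peaks[0]])

    return SignalMetrics(
        mean=mean,
        peak_to_peak=p2p,
        dominant_frequency=dom,
        first_peak_time=first_peak,
    )
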