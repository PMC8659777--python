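"""Synthetic arm-swing magnetometer traces and the gait-frequency model.

During walking the arm swings like a pendulum, out of phase with the legs,
and a wrist-worn magnetometer moving through the Earth's field records a
periodic modulation of the measured field components.  This module provides

* :func:`step_frequency` — the stride-frequency model
  ``f = walk_speed / stride_length`` (speed in m/s), which places normal
  walking at roughly 0.85–1.38 Hz for 4–6.5 km/h and a 1.3 m stride;
* :func:`simulate_trace` — a seeded generator of single-axis (Z) traces
  with known ground-truth step times, emulating walking as a sinusoidal
  field modulation at the stride frequency (one peak and one valley per
  stride cycle, i.e. one extremum per step), standing as a constant field,
  plus sensor noise, quantisation and optional ambient disturbance pulses;
* :func:`spectrum` — magnitude spectrum of a trace, for inspecting where
  the gait energy sits relative to the low-pass cutoff.

Everything downstream (buffering, filtering, detection, evaluation) is
exercised against these traces, so the generator keeps an explicit truth
channel (:class:`GroundTruth`) alongside the samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorSpec",
    "Segment",
    "Disturbance",
    "GaitSimConfig",
    "SampleSeries",
    "GroundTruth",
    "step_frequency",
    "simulate_trace",
    "spectrum",
    "read_trace_csv",
    "write_trace_csv",
    "read_truth_csv",
    "write_truth_csv",
]

KMH_TO_MS = 1.0 / 3.6


@dataclass(frozen=True)
class SensorSpec:
    """Datasheet parameters of the digital magnetometer.

    Defaults follow a wrist-worn 3-axis sensor sampling at 40 Hz with a
    ±1000 µT range, 16-bit resolution, 0.1 µT/LSB sensitivity and a
    0.25 µT RMS noise floor.
    """

    sampling_hz: float = 40.0
    resolution_bits: int = 16
    full_range_uT: float = 1000.0
    sensitivity_uT_per_lsb: float = 0.1
    noise_sigma_uT: float = 0.25

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.sensitivity_uT_per_lsb <= 0:
            raise ValueError("sensitivity_uT_per_lsb must be positive")
        if self.noise_sigma_uT < 0:
            raise ValueError("noise_sigma_uT must be non-negative")
        counts_needed = 2.0 * self.full_range_uT / self.sensitivity_uT_per_lsb
        if counts_needed > 2**self.resolution_bits:
            warnings.warn(
                f"full range ±{self.full_range_uT} µT at "
                f"{self.sensitivity_uT_per_lsb} µT/LSB needs "
                f"{counts_needed:.0f} counts, more than "
                f"{self.resolution_bits} bits provide",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Segment:
    """One activity segment: ``state`` is ``"walking"`` or ``"standing"``."""

    state: str
    duration_s: float

    def __post_init__(self) -> None:
        if self.state not in ("walking", "standing"):
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class Disturbance:
    """Additive Gaussian-shaped ambient field pulse.

    ``amplitude_uT * exp(-(t - time_s)^2 / (2 width_s^2))`` is added to the
    Z trace; models a transient from nearby electronics or ferrous objects.
    """

    time_s: float
    amplitude_uT: float
    width_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("disturbance width must be positive")


@dataclass(frozen=True)
class GaitSimConfig:
    """Ground-truth gait parameters for the synthetic trace generator.

    Parameters
    ----------
    walk_speed_kmh
        Average walking speed; normal gait spans roughly 4–6.5 km/h.
    stride_length_m
        Full gait-cycle length (two steps); 1.3 m is the adult average.
    field_mean_uT
        Baseline Z-axis field (Earth field projection at the wrist).
    swing_amplitude_uT
        Peak field deviation ΔB of the arm-swing modulation.  Must exceed
        twice the fake-step threshold (0.5 µT) for the walk to be reliably
        detectable.
    segments
        Ordered activity segments; concatenated in time.
    disturbances
        Ambient pulses added on top of the clean trace.
    phase_rad
        Initial swing phase of each walking segment.
    double_frequency_fraction
        Optional amplitude fraction of a component at twice the stride
        frequency (a swing whose field peaks at both arm endpoints); 0
        keeps the pure stride-frequency model used throughout the tests.
    quantize
        Round samples to the sensor's 0.1 µT/LSB grid, emulating the ADC.
    """

    walk_speed_kmh: float = 5.0
    stride_length_m: float = 1.3
    field_mean_uT: float = 48.0
    swing_amplitude_uT: float = 5.0
    segments: tuple[Segment, ...] = (Segment("walking", 60.0),)
    disturbances: tuple[Disturbance, ...] = ()
    phase_rad: float = 0.0
    double_frequency_fraction: float = 0.0
    quantize: bool = True
    seed: int = 0
    sensor: SensorSpec = field(default_factory=SensorSpec)

    def __post_init__(self) -> None:
        if self.walk_speed_kmh < 0:
            raise ValueError("walk_speed_kmh must be non-negative")
        if self.stride_length_m <= 0:
            raise ValueError("stride_length_m must be positive")
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        dists = tuple(
            d if isinstance(d, Disturbance) else Disturbance(*d)
            for d in self.disturbances
        )
        object.__setattr__(self, "disturbances", dists)

    @property
    def stride_frequency_hz(self) -> float:
        return step_frequency(self.walk_speed_kmh, self.stride_length_m)


@dataclass(frozen=True)
class SampleSeries:
    """Uniformly sampled single-axis magnetic field trace."""

    values: np.ndarray
    sampling_hz: float
    start_time: float = 0.0
    units: str = "uT"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.units not in ("uT", "lsb"):
            raise ValueError("units must be 'uT' or 'lsb'")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sampling_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_hz

    def to_lsb(self, sensitivity_uT_per_lsb: float = 0.1) -> "SampleSeries":
        """Convert µT → integer sensor counts (rounded)."""
        if self.units == "lsb":
            return self
        counts = np.round(self.values / sensitivity_uT_per_lsb)
        return replace(self, values=counts, units="lsb")

    def to_ut(self, sensitivity_uT_per_lsb: float = 0.1) -> "SampleSeries":
        """Convert integer sensor counts → µT."""
        if self.units == "uT":
            return self
        return replace(
            self, values=self.values * sensitivity_uT_per_lsb, units="uT"
        )


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel of the simulator: step times and per-sample activity."""

    step_times: np.ndarray
    segment_labels: np.ndarray  # per-sample, "walking" or "standing"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "step_times", np.asarray(self.step_times, dtype=np.float64)
        )
        object.__setattr__(
            self, "segment_labels", np.asarray(self.segment_labels)
        )
        if np.any(np.diff(self.step_times) <= 0):
            raise ValueError("step_times must be strictly increasing")

    @property
    def step_count(self) -> int:
        return len(self.step_times)


def step_frequency(walk_speed_kmh: float, stride_length_m: float) -> float:
    """Stride frequency in Hz from walking speed and stride length.

    ``f = v / L`` with ``v`` in m/s (km/h divided by 3.6) and ``L`` the
    stride (full gait cycle) length in metres.  Each stride contains two
    steps, so the step rate is ``2 f``.

    >>> round(step_frequency(4.0, 1.3), 4)
    0.8547
    """
    if stride_length_m <= 0:
        raise ValueError("stride_length_m must be positive")
    if walk_speed_kmh < 0:
        raise ValueError("walk_speed_kmh must be non-negative")
    return (walk_speed_kmh * KMH_TO_MS) / stride_length_m


def _walking_waveform(
    tau: np.ndarray, f: float, amplitude: float, phase: float, double_frac: float
) -> np.ndarray:
    """Clean arm-swing modulation on segment-local time ``tau``."""
    b = amplitude * np.sin(2.0 * math.pi * f * tau + phase)
    if double_frac:
        b = b + amplitude * double_frac * np.sin(
            4.0 * math.pi * f * tau + 2.0 * phase
        )
    return b


def _segment_step_times(
    t0: float, duration: float, f: float, phase: float, double_frac: float
) -> np.ndarray:
    """Extremum times of the clean waveform inside [t0, t0 + duration).

    For the pure sinusoid the extrema solve ``cos(2πf τ + φ) = 0``:
    ``τ_k = (π/2 + kπ − φ) / (2πf)``.  With the optional doubled-frequency
    term the extrema are found numerically on a dense grid.
    """
    if f <= 0:
        return np.empty(0)
    if not double_frac:
        # smallest k giving τ_k >= 0
        k0 = math.ceil((phase - math.pi / 2.0) / math.pi)
        ks = []
        k = k0
        while True:
            tau = (math.pi / 2.0 + k * math.pi - phase) / (2.0 * math.pi * f)
            if tau >= duration:
                break
            if tau >= 0:
                ks.append(tau)
            k += 1
        return t0 + np.asarray(ks)
    # numeric fallback: derivative sign changes on a fine grid
    n = max(int(duration * f * 200), 50)
    tau = np.linspace(0.0, duration, n, endpoint=False)
    b = _walking_waveform(tau, f, 1.0, phase, double_frac)
    d = np.diff(b)
    idx = np.nonzero(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1
    return t0 + tau[idx]


def simulate_trace(
    config: GaitSimConfig,
) -> tuple[SampleSeries, GroundTruth]:
    """Generate a synthetic Z-axis trace with its ground truth.

    Walking segments carry ``field_mean + ΔB sin(2πf τ + φ)`` where ``f``
    is the stride frequency; each extremum of the clean waveform (one peak
    and one valley per period) is one ground-truth step, giving two steps
    per stride cycle.  Standing segments are the constant baseline.
    White Gaussian sensor noise, optional disturbance pulses and ADC
    quantisation are applied on top.  Identical config (including seed)
    yields a bitwise-identical trace.
    """
    fs = config.sensor.sampling_hz
    rng = np.random.default_rng(config.seed)

    total = sum(s.duration_s for s in config.segments)
    n = int(round(total * fs))
    t = np.arange(n) / fs
    clean = np.full(n, config.field_mean_uT, dtype=np.float64)
    labels = np.empty(n, dtype=object)

    f = config.stride_frequency_hz
    step_times: list[np.ndarray] = []
    t0 = 0.0
    for seg in config.segments:
        i0 = int(round(t0 * fs))
        i1 = int(round((t0 + seg.duration_s) * fs))
        labels[i0:i1] = seg.state
        if seg.state == "walking" and f > 0:
            tau = t[i0:i1] - t0
            clean[i0:i1] += _walking_waveform(
                tau,
                f,
                config.swing_amplitude_uT,
                config.phase_rad,
                config.double_frequency_fraction,
            )
            step_times.append(
                _segment_step_times(
                    t0,
                    seg.duration_s,
                    f,
                    config.phase_rad,
                    config.double_frequency_fraction,
                )
            )
        t0 += seg.duration_s

    for d in config.disturbances:
        clean += d.amplitude_uT * np.exp(
            -((t - d.time_s) ** 2) / (2.0 * d.width_s**2)
        )

    values = clean
    if config.sensor.noise_sigma_uT > 0:
        values = values + rng.normal(0.0, config.sensor.noise_sigma_uT, n)
    if config.quantize:
        q = config.sensor.sensitivity_uT_per_lsb
        values = np.round(values / q) * q

    series = SampleSeries(values=values, sampling_hz=fs)
    all_steps = (
        np.concatenate(step_times) if step_times else np.empty(0)
    )
    truth = GroundTruth(step_times=all_steps, segment_labels=labels)
    return series, truth


def spectrum(series: SampleSeries) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of the mean-removed trace.

    Returns ``(frequencies_hz, magnitudes)`` up to the Nyquist frequency.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    x = series.values - np.mean(series.values)
    mags = np.abs(np.fft.rfft(x)) / len(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / series.sampling_hz)
    return freqs, mags


# ---------------------------------------------------------------------------
# CSV interchange: trace files carry all three axes (bx, by filled with the
# baseline unless extended); the ground-truth sidecar is one column of step
# times in seconds.

def write_trace_csv(
    path, series: SampleSeries, field_mean_uT: float | None = None
) -> None:
    s = series.to_ut() if series.units == "lsb" else series
    mean = field_mean_uT if field_mean_uT is not None else float(
        np.mean(s.values) if len(s) else 0.0
    )
    pd.DataFrame(
        {
            "time_s": s.times,
            "bx_uT": np.full(len(s), mean),
            "by_uT": np.full(len(s), mean),
            "bz_uT": s.values,
        }
    ).to_csv(path, index=False)


def read_trace_csv(path, axis: str = "z") -> SampleSeries:
    df = pd.read_csv(path)
    col = f"b{axis.lower()}_uT"
    if col not in df.columns:
        raise ValueError(f"column {col!r} not present in {path}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace must have at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")
    return SampleSeries(
        values=df[col].to_numpy(),
        sampling_hz=1.0 / float(dt[0]),
        start_time=float(t[0]),
    )


def write_truth_csv(path, truth: GroundTruth) -> None:
    pd.DataFrame({"step_time_s": truth.step_times}).to_csv(path, index=False)


def read_truth_csv(path) -> np.ndarray:
    return pd.read_csv(path)["step_time_s"].to_numpy()
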