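"""Synthesis of multi-echo ultrasonic A-scan traces.

A single-element transducer insonifies a monodimensional path through a
scattering medium.  Each scatterer returns a replica of the emitted pulse
delayed by its two-way travel time; the recorded trace is the superposition
of those replicas.  Two scatterer geometries are supported:

* a *regular* lattice with constant spacing ``d`` (echo m arrives at
  ``2 m d / v``), and
* a *stochastic* field whose inter-arrival times are i.i.d. gamma draws,
  parameterised by their mean and variance (method of moments:
  ``shape = mean^2 / var``, ``scale = var / mean``).

Far-field, attenuation-free, dispersion-free propagation is assumed, so the
echo waveform equals the emitted pulse.  Echo arrival times are evaluated on
a continuous time axis (never quantised to the sample grid): thermal
perturbations move arrivals by far less than one sample period, and that
sub-sample motion is the entire thermometry signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any, Mapping

import numpy as np

from .errors import ConfigurationError
from .thermal import TissueThermalModel

#: Default sampling-rate multiple of (f0 + bandwidth).
DEFAULT_RATE_FACTOR = 8.0

#: Default pulse support in units of 1/bandwidth; the Gaussian-like envelope
#: exp(-4 w^2 t^2) has decayed to ~1e-7 at t = 2/w.
DEFAULT_PULSE_SUPPORT_FACTOR = 2.0

#: Default number of scatterers along the insonified path.
DEFAULT_SCATTERER_COUNT = 64


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransducerPulse:
    """Emitted unitary pulse ``P(t) = -t exp(-4 w^2 t^2) sin(2 pi f0 t)``.

    ``w`` (``bandwidth``) and ``f0`` (``center_frequency``) are both plain
    frequencies in Hz; there is no 2*pi factor inside the envelope exponent.
    The pulse is identically zero for ``t <= 0``.
    """

    center_frequency: float
    bandwidth: float
    duration: float | None = None
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ConfigurationError("center_frequency must be positive")
        if not self.bandwidth > 0:
            raise ConfigurationError("bandwidth must be positive")
        if self.duration is None:
            object.__setattr__(
                self, "duration", DEFAULT_PULSE_SUPPORT_FACTOR / self.bandwidth
            )
        if self.sampling_rate is None:
            object.__setattr__(
                self,
                "sampling_rate",
                DEFAULT_RATE_FACTOR * (self.center_frequency + self.bandwidth),
            )
        if not self.sampling_rate > 2.0 * (self.center_frequency + self.bandwidth):
            raise ConfigurationError(
                "sampling_rate must exceed 2 * (center_frequency + bandwidth); "
                f"got {self.sampling_rate:g} for f0 + w = "
                f"{self.center_frequency + self.bandwidth:g}"
            )
        if not self.duration > 0:
            raise ConfigurationError("duration must be positive")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the pulse on an arbitrary (continuous) time axis in s.

        Support is ``(0, duration]``; the envelope has decayed to ~1e-7 of
        its peak at the default duration, so truncation is inaudible.
        """
        t = np.asarray(t, dtype=float)
        w, f0 = self.bandwidth, self.center_frequency
        out = -t * np.exp(-4.0 * w * w * t * t) * np.sin(2.0 * np.pi * f0 * t)
        return np.where((t > 0) & (t <= self.duration), out, 0.0)


@dataclass(frozen=True)
class RegularScattererField:
    """Evenly spaced scatterer lattice: scatterer m sits at depth ``m d``."""

    mean_spacing: float
    count: int = DEFAULT_SCATTERER_COUNT
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.mean_spacing > 0:
            raise ConfigurationError("mean_spacing must be positive")
        if self.count < 1:
            raise ConfigurationError("count must be >= 1")
        amps = self.amplitudes
        if amps is None:
            amps = np.ones(self.count)
        amps = np.asarray(amps, dtype=float)
        if amps.shape != (self.count,):
            raise ConfigurationError("amplitudes length must equal count")
        if not np.all(np.isfinite(amps)):
            raise ConfigurationError("amplitudes must be finite")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def depths(self) -> np.ndarray:
        """Baseline scatterer depths ``m d`` for m = 1..count, metres."""
        return self.mean_spacing * np.arange(1, self.count + 1)


@dataclass(frozen=True)
class StochasticScattererField:
    """Scatterer field with gamma-distributed echo inter-arrival times.

    ``amplitude_law`` is either ``("constant", value)`` or
    ``("uniform", lo, hi)``; echo amplitudes are drawn i.i.d. from it.
    """

    mean_interarrival: float
    interarrival_variance: float
    count: int = DEFAULT_SCATTERER_COUNT
    amplitude_law: tuple = ("uniform", 0.5, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_interarrival > 0:
            raise ConfigurationError("mean_interarrival must be positive")
        if self.interarrival_variance < 0:
            raise ConfigurationError("interarrival_variance must be >= 0")
        if self.count < 1:
            raise ConfigurationError("count must be >= 1")
        kind = self.amplitude_law[0]
        if kind not in ("constant", "uniform"):
            raise ConfigurationError(f"unknown amplitude law {kind!r}")

    @property
    def gamma_shape(self) -> float:
        """Method-of-moments gamma shape ``mean^2 / variance``."""
        if self.interarrival_variance == 0:
            raise ConfigurationError("degenerate field (variance 0) has no gamma shape")
        return self.mean_interarrival**2 / self.interarrival_variance

    @property
    def gamma_scale(self) -> float:
        """Method-of-moments gamma scale ``variance / mean``."""
        if self.interarrival_variance == 0:
            raise ConfigurationError("degenerate field (variance 0) has no gamma scale")
        return self.interarrival_variance / self.mean_interarrival


@dataclass(frozen=True)
class EchoTrace:
    """Sampled A-scan with its sampling rate and provenance metadata."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    metadata: Mapping[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("trace samples must be finite")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample time axis in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class EchoSchedule:
    """Continuous echo arrival times (s) and amplitudes for one trace."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if times.shape != amps.shape:
            raise ConfigurationError("times and amplitudes must have equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", amps)


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant axial temperature change dT(z).

    ``z_edges`` are the segment boundaries in metres (length k+1, starting at
    0 and strictly increasing); ``delta_t`` holds the k per-segment
    temperature changes in degC.
    """

    z_edges: np.ndarray
    delta_t: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_edges, dtype=float)
        dt = np.asarray(self.delta_t, dtype=float)
        if z.ndim != 1 or z.size < 2 or dt.size != z.size - 1:
            raise ConfigurationError("need k+1 edges for k segments")
        if z[0] != 0.0 or np.any(np.diff(z) <= 0):
            raise ConfigurationError("z_edges must start at 0 and strictly increase")
        object.__setattr__(self, "z_edges", z)
        object.__setattr__(self, "delta_t", dt)

    @classmethod
    def uniform(cls, delta_t: float, z_max: float) -> "TemperatureProfile":
        return cls(np.array([0.0, z_max]), np.array([float(delta_t)]))

    @property
    def z_max(self) -> float:
        return float(self.z_edges[-1])


# ---------------------------------------------------------------------------
# Pulse and trace synthesis
# ---------------------------------------------------------------------------


def emit_pulse(pulse: TransducerPulse) -> EchoTrace:
    """Sample the emitted unitary pulse on ``[0, duration]``."""
    n = int(round(pulse.duration * pulse.sampling_rate)) + 1
    t = np.arange(n) / pulse.sampling_rate
    return EchoTrace(
        samples=pulse.waveform(t),
        sampling_rate=pulse.sampling_rate,
        metadata={
            "kind": "pulse",
            "center_frequency_hz": pulse.center_frequency,
            "bandwidth_hz": pulse.bandwidth,
        },
    )


def synthesize_schedule_trace(
    pulse: TransducerPulse,
    schedule: EchoSchedule,
    duration: float | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> EchoTrace:
    """Superpose pulse replicas at the scheduled (continuous) arrival times."""
    fs = pulse.sampling_rate
    last = float(np.max(schedule.times)) if schedule.times.size else 0.0
    if duration is None:
        duration = last + 4.0 * pulse.duration
    elif duration < last:
        raise ConfigurationError(
            f"trace duration {duration:g} s shorter than last echo arrival "
            f"{last:g} s; need at least {last + pulse.duration:g} s"
        )
    n = int(round(duration * fs))
    out = np.zeros(n)
    support = int(np.ceil(pulse.duration * fs)) + 1
    for t_m, a_m in zip(schedule.times, schedule.amplitudes):
        i0 = max(int(np.floor(t_m * fs)), 0)
        i1 = min(i0 + support + 1, n)
        if i0 >= n:
            continue
        t_local = np.arange(i0, i1) / fs - t_m
        out[i0:i1] += a_m * pulse.waveform(t_local)
    meta = dict(metadata or {})
    meta.setdefault("n_echoes", int(schedule.times.size))
    return EchoTrace(samples=out, sampling_rate=fs, metadata=meta)


def synthesize_regular_trace(
    pulse: TransducerPulse,
    field: RegularScattererField,
    sound_speed: float,
    duration: float | None = None,
) -> EchoTrace:
    """Trace from a regular lattice: echo m arrives at ``2 m d / v``."""
    if not sound_speed > 0:
        raise ConfigurationError("sound_speed must be positive")
    times = 2.0 * field.depths / sound_speed
    schedule = EchoSchedule(times=times, amplitudes=field.amplitudes)
    return synthesize_schedule_trace(
        pulse,
        schedule,
        duration=duration,
        metadata={
            "kind": "regular",
            "mean_spacing_m": field.mean_spacing,
            "sound_speed_m_s": sound_speed,
        },
    )


def synthesize_stochastic_trace(
    pulse: TransducerPulse,
    field: StochasticScattererField,
    sound_speed: float = 1540.0,
    duration: float | None = None,
) -> EchoTrace:
    """Trace with gamma inter-arrival times; deterministic given the seed.

    With zero variance the inter-arrival distribution degenerates to a
    constant and the result equals a regular trace with
    ``d = v * mean_interarrival / 2``.
    """
    rng = np.random.default_rng(field.rng_seed)
    if field.interarrival_variance == 0:
        taus = np.full(field.count, field.mean_interarrival)
    else:
        taus = rng.gamma(field.gamma_shape, field.gamma_scale, size=field.count)
    times = np.cumsum(taus)
    law = field.amplitude_law
    if law[0] == "constant":
        amps = np.full(field.count, float(law[1]))
    else:
        amps = rng.uniform(law[1], law[2], size=field.count)
    schedule = EchoSchedule(times=times, amplitudes=amps)
    return synthesize_schedule_trace(
        pulse,
        schedule,
        duration=duration,
        metadata={
            "kind": "stochastic",
            "mean_interarrival_s": field.mean_interarrival,
            "interarrival_variance_s2": field.interarrival_variance,
            "rng_seed": field.rng_seed,
            "sound_speed_m_s": sound_speed,
        },
    )


def add_noise(trace: EchoTrace, snr_db: float, rng_seed: int) -> EchoTrace:
    """Add zero-mean white Gaussian noise at a requested SNR in dB.

    Noise power is ``signal_power / 10^(snr_db / 10)`` with the signal power
    taken as the mean squared sample over the whole trace support.
    """
    if not np.isfinite(snr_db):
        raise ConfigurationError("snr_db must be finite")
    if len(trace) == 0:
        raise ConfigurationError("cannot add noise to an empty trace")
    signal_power = float(np.mean(trace.samples**2))
    if signal_power == 0:
        raise ConfigurationError("all-zero trace: signal power undefined")
    noise_power = signal_power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, np.sqrt(noise_power), size=len(trace))
    meta = dict(trace.metadata)
    meta.update({"snr_db": float(snr_db), "noise_seed": int(rng_seed)})
    return EchoTrace(
        samples=trace.samples + noise,
        sampling_rate=trace.sampling_rate,
        start_time=trace.start_time,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Thermal perturbation of echo timing
# ---------------------------------------------------------------------------


def apply_thermal_state(
    field: RegularScattererField,
    thermal: TissueThermalModel,
    profile: "TemperatureProfile | float",
) -> EchoSchedule:
    """Echo arrival-time schedule for a thermally perturbed lattice.

    Each depth segment of the piecewise-constant profile dilates by
    ``(1 + alpha dT_seg)`` and propagates sound at ``v0 + (dv/dT) dT_seg``;
    an echo's arrival time is twice the sum of segment traversal times down
    to its scatterer.  For a uniform ``dT`` this reduces to
    ``t_m = 2 m d0 (1 + alpha dT) / v(dT)``, whose implied inter-arrival
    resonance is exactly the exact overtone law.
    """
    depths = field.depths
    if not isinstance(profile, TemperatureProfile):
        profile = TemperatureProfile.uniform(float(profile), float(depths[-1]))
    if profile.z_max < depths[-1] - 1e-12 * field.mean_spacing:
        raise ConfigurationError(
            f"profile extends to {profile.z_max:g} m but the field reaches "
            f"{depths[-1]:g} m"
        )
    alpha = thermal.expansion_coeff
    base_thickness = np.diff(profile.z_edges)
    speeds = thermal.base_speed + thermal.speed_slope * profile.delta_t
    if np.any(speeds <= 0):
        raise ConfigurationError("thermal state implies non-positive sound speed")
    # One-way traversal time of each (dilated) full segment.
    seg_times = base_thickness * (1.0 + alpha * profile.delta_t) / speeds
    cum_times = np.concatenate([[0.0], np.cumsum(seg_times)])
    idx = np.clip(np.searchsorted(profile.z_edges, depths, side="right") - 1, 0,
                  profile.delta_t.size - 1)
    partial = (depths - profile.z_edges[idx]) * (
        1.0 + alpha * profile.delta_t[idx]
    ) / speeds[idx]
    times = 2.0 * (cum_times[idx] + partial)
    return EchoSchedule(times=times, amplitudes=field.amplitudes)


def synthesize_heated_trace(
    pulse: TransducerPulse,
    field: RegularScattererField,
    thermal: TissueThermalModel,
    profile: "TemperatureProfile | float",
    duration: float | None = None,
) -> EchoTrace:
    """Regular-lattice trace under a thermal perturbation of the echo timing."""
    schedule = apply_thermal_state(field, thermal, profile)
    meta = {
        "kind": "regular-heated",
        "mean_spacing_m": field.mean_spacing,
        "sound_speed_m_s": thermal.base_speed,
    }
    if not isinstance(profile, TemperatureProfile):
        meta["delta_t_c"] = float(profile)
    return synthesize_schedule_trace(pulse, schedule, duration=duration, metadata=meta)
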