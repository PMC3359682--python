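"""Thermometry pipeline: traces -> extended Burg spectra -> overtone
tracking -> temperature-change estimates.

The observable is the location of one overtone of the scatterer-spacing
resonance in each trace's (or each window's) high-resolution AR spectrum.
Successive peak shifts are converted to temperature changes through the
linear shift law; because peaks are read on the ``fs / Nf`` grid, estimates
are quantised to the temperature equivalent of one grid step, which is
carried alongside every estimate as its resolution context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PeakLostError
from .simulate import EchoTrace
from .spectral import extended_burg_psd, find_peak_near, segment_trace
from .thermal import (
    HarmonicSelection,
    TissueThermalModel,
    harmonic_shift,
    invert_shift_to_temperature,
)

#: Search-band half-width as a fraction of the fundamental: wide enough to
#: follow thermal drift, narrow enough never to hop to an adjacent overtone.
SEARCH_BAND_FRACTION = 0.45


@dataclass(frozen=True)
class HarmonicTrack:
    """Peak locations of one overtone across an ordered trace series."""

    harmonic_index: int
    temperatures: np.ndarray
    peak_frequencies: np.ndarray
    shifts: np.ndarray
    grid_step: float

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        p = np.asarray(self.peak_frequencies, dtype=float)
        s = np.asarray(self.shifts, dtype=float)
        if not (t.shape == p.shape == s.shape):
            raise ConfigurationError("track vectors must have equal length")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "peak_frequencies", p)
        object.__setattr__(self, "shifts", s)

    @property
    def step_shifts(self) -> np.ndarray:
        """Successive (per-step) peak displacements in Hz."""
        return np.diff(self.peak_frequencies)


@dataclass(frozen=True)
class ThermometryEstimate:
    """One temperature-change estimate with its quantisation context."""

    delta_t: float
    residual: float
    grid_step: float

    def __post_init__(self) -> None:
        if abs(self.residual) > self.grid_step + 1e-9:
            raise ConfigurationError("residual exceeds one grid step")


def _band_peak(psd, expected: float, half_width: float, index: int) -> float:
    """Locate a peak and verify it stands above the in-band median power."""
    mask = (psd.frequencies >= expected - half_width) & (
        psd.frequencies <= expected + half_width
    )
    if not np.any(mask):
        raise PeakLostError(f"trace {index}: search band misses the PSD grid")
    band = psd.power[mask]
    if band.max() <= np.median(band):
        raise PeakLostError(
            f"trace {index}: no peak above the in-band median power"
        )
    return find_peak_near(psd, expected, half_width)


def track_harmonic(
    traces: Sequence[EchoTrace],
    selection: HarmonicSelection,
    fundamental: float,
    pad_factor: int = 1,
    order: int | None = None,
    search_half_width: float | None = None,
) -> HarmonicTrack:
    """Follow one overtone peak through an ordered series of traces.

    Each trace is zero-extended, Burg-fitted and evaluated on the common
    ``fs / Nf`` grid; the search band is recentred on the previous peak so
    the track follows thermal drift.  Trace temperatures are taken from the
    ``temperature_c`` metadata key when present.
    """
    if len(traces) < 2:
        raise ConfigurationError("need at least two traces to track")
    lengths = {len(t) for t in traces}
    rates = {t.sampling_rate for t in traces}
    if len(lengths) != 1 or len(rates) != 1:
        raise ConfigurationError("traces must share length and sampling rate")
    if search_half_width is None:
        search_half_width = SEARCH_BAND_FRACTION * fundamental
    peaks = []
    temps = []
    expected = selection.expected_frequency
    grid_step = None
    for i, trace in enumerate(traces):
        psd, _ = extended_burg_psd(
            trace.samples, trace.sampling_rate, pad_factor=pad_factor, order=order
        )
        grid_step = psd.grid_step
        peak = _band_peak(psd, expected, search_half_width, i)
        peaks.append(peak)
        temps.append(float(trace.metadata.get("temperature_c", i)))
        expected = peak  # recentre on the drifting peak
    peaks = np.asarray(peaks)
    return HarmonicTrack(
        harmonic_index=selection.harmonic_index,
        temperatures=np.asarray(temps),
        peak_frequencies=peaks,
        shifts=peaks - peaks[0],
        grid_step=float(grid_step),
    )


def estimate_temperature_steps(
    track: HarmonicTrack, model: TissueThermalModel
) -> list[ThermometryEstimate]:
    """Per-step temperature-change estimates from successive peak shifts."""
    estimates = []
    for shift in track.step_shifts:
        delta_t = invert_shift_to_temperature(model, track.harmonic_index, shift)
        residual = shift - harmonic_shift(model, track.harmonic_index, delta_t)
        estimates.append(
            ThermometryEstimate(
                delta_t=float(delta_t),
                residual=float(residual),
                grid_step=track.grid_step,
            )
        )
    return estimates


def estimate_thermal_profile(
    baseline: EchoTrace,
    heated: EchoTrace,
    n_windows: int,
    selection: HarmonicSelection,
    model: TissueThermalModel,
    window_length: int | None = None,
    pad_factor: int = 1,
    order: int | None = None,
    search_half_width: float | None = None,
) -> pd.DataFrame:
    """Per-window (depth-resolved) temperature-change profile.

    Both traces are segmented identically; each window pair yields a local
    overtone shift (heated vs baseline, window against same window) which is
    inverted to a local temperature change.  Returns a depth-indexed table
    with columns ``window_index, depth_m, peak_baseline_hz, peak_heated_hz,
    shift_hz, delta_t_c, grid_step_hz``.
    """
    if len(baseline) != len(heated) or baseline.sampling_rate != heated.sampling_rate:
        raise ConfigurationError("baseline and heated traces must be aligned")
    if window_length is None:
        window_length = len(baseline) // n_windows
    min_len = 2 * (order if order is not None else 2) + 2
    if window_length < min_len:
        raise ConfigurationError(
            f"window of {window_length} samples too short for the AR order; "
            f"need at least {min_len} samples"
        )
    if search_half_width is None:
        search_half_width = SEARCH_BAND_FRACTION * model.fundamental
    win_base = segment_trace(
        baseline, n_windows, window_length, pad_factor, model.base_speed
    )
    win_heat = segment_trace(
        heated, n_windows, window_length, pad_factor, model.base_speed
    )
    rows = []
    for wb, wh in zip(win_base, win_heat):
        psd_b, _ = extended_burg_psd(
            wb.samples, baseline.sampling_rate, pad_factor=pad_factor, order=order
        )
        psd_h, _ = extended_burg_psd(
            wh.samples, heated.sampling_rate, pad_factor=pad_factor, order=order
        )
        peak_b = _band_peak(
            psd_b, selection.expected_frequency, search_half_width, wb.window_index
        )
        peak_h = _band_peak(psd_h, peak_b, search_half_width, wh.window_index)
        shift = peak_h - peak_b
        delta_t = invert_shift_to_temperature(model, selection.harmonic_index, shift)
        rows.append(
            {
                "window_index": wb.window_index,
                "depth_m": wb.start_depth,
                "peak_baseline_hz": peak_b,
                "peak_heated_hz": peak_h,
                "shift_hz": shift,
                "delta_t_c": delta_t,
                "grid_step_hz": psd_b.grid_step,
            }
        )
    return pd.DataFrame(rows)
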