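"""Shared fixtures: small, fast synthetic configurations.

The unit tests run on scaled-down transducer/lattice geometries; the
full reference configurations of the evaluation studies are exercised in
``test_acceptance.py``.
"""

import numpy as np
import pytest

import echotherm as et

SOUND_SPEED = 1540.0


@pytest.fixture
def small_pulse() -> et.TransducerPulse:
    """2.25 MHz / 1 MHz pulse — the classic imaging-band example."""
    return et.TransducerPulse(center_frequency=2.25e6, bandwidth=1e6)


@pytest.fixture
def liver_model() -> et.TissueThermalModel:
    """1.1 mm lattice: fundamental 700 kHz at 1540 m/s."""
    return et.TissueThermalModel(base_spacing=1.1e-3, base_temperature=30.0)


@pytest.fixture
def comb_setup():
    """A compact comb configuration: 0.77 mm lattice (f1 = 1 MHz) viewed by
    a 10 MHz transducer, cheap enough for repeated Burg fits."""
    thermal = et.TissueThermalModel(base_spacing=0.77e-3, base_temperature=30.0)
    pulse = et.TransducerPulse(center_frequency=10e6, bandwidth=2e6)
    field = et.RegularScattererField(mean_spacing=0.77e-3, count=48)
    return thermal, pulse, field


def make_heated_series(thermal, pulse, field, delta_ts, duration=None):
    """Noise-free heated traces at the given temperature offsets."""
    if duration is None:
        t_last = 2.0 * field.count * field.mean_spacing / thermal.base_speed
        duration = t_last * 1.001 + 4.0 * pulse.duration
    traces = []
    for dt in delta_ts:
        tr = et.synthesize_heated_trace(pulse, field, thermal, dt, duration=duration)
        tr.metadata["temperature_c"] = thermal.base_temperature + dt
        traces.append(tr)
    return traces
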