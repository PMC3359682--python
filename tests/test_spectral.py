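"""AR spectral estimation: Yule-Walker, Burg, PSD evaluation, register
zero-extension, segmentation, peak reading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lfilter, periodogram
from statsmodels.regression.linear_model import yule_walker as sm_yule_walker

import echotherm as et
from echotherm.errors import ConfigurationError, MemoryGuardError, NumericalError
from echotherm.spectral import band_peak_stats, extended_burg_psd, suggest_ar_order


def ar_process(coeffs, n, seed=0, sigma=1.0):
    """Generate x(n) = -sum a_k x(n-k) + w(n) with unit-variance drive."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, sigma, size=n + 500)
    x = lfilter([1.0], np.concatenate([[1.0], coeffs]), w)
    return x[500:]


# ---------------------------------------------------------------------------
# Yule-Walker
# ---------------------------------------------------------------------------


def test_yule_walker_white_noise_is_nearly_flat():
    rng = np.random.default_rng(3)
    x = rng.normal(size=100_000)
    model = et.yule_walker_fit(x, 4)
    assert np.all(np.abs(model.coefficients) < 0.02)
    assert model.residual_power == pytest.approx(np.var(x), rel=0.1)


def test_yule_walker_recovers_ar1():
    x = ar_process([-0.8], 100_000, seed=4)
    model = et.yule_walker_fit(x, 1)
    assert model.coefficients[0] == pytest.approx(-0.8, abs=0.02)


def test_yule_walker_matches_statsmodels_oracle():
    """Independent route: statsmodels' MLE (biased-acf) Yule-Walker."""
    x = ar_process([-1.2, 0.6], 20_000, seed=5)
    model = et.yule_walker_fit(x, 2)
    rho, sigma = sm_yule_walker(x, order=2, method="mle", demean=False)
    np.testing.assert_allclose(model.coefficients, -rho, atol=1e-8)
    assert model.residual_power == pytest.approx(sigma**2, rel=1e-6)


def test_yule_walker_rejects_bad_inputs():
    with pytest.raises(ConfigurationError):
        et.yule_walker_fit(np.arange(100.0), 0)
    with pytest.raises(NumericalError):
        et.yule_walker_fit(np.full(100, 2.5), 2)


# ---------------------------------------------------------------------------
# Burg
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), order=st.integers(1, 12))
def test_burg_reflection_coefficients_bounded(seed, order):
    """Burg's harmonic-mean denominator guarantees |K_m| <= 1, hence a
    stable all-pole model, for arbitrary input data."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=256) * rng.uniform(0.1, 100)
    model = et.burg_fit(x, order)
    assert np.all(np.abs(model.reflection_coefficients) <= 1.0 + 1e-12)
    assert np.all(np.abs(model.poles()) <= 1.0 + 1e-9)


def test_burg_locates_single_sinusoid():
    """Order-2 fit of a sinusoid at fs/8: pole angle within one grid step."""
    fs = 1000.0
    n = 4096
    t = np.arange(n) / fs
    rng = np.random.default_rng(6)
    x = np.sin(2 * np.pi * (fs / 8) * t) + 1e-3 * rng.normal(size=n)
    model = et.burg_fit(x, 2)
    psd = et.ar_psd(model, fs, n // 2 + 1)
    pole_freq = abs(np.angle(model.poles()[0])) * fs / (2 * np.pi)
    assert abs(pole_freq - fs / 8) <= psd.grid_step


def test_burg_recovers_ar2_poles_at_radius_095():
    r, theta = 0.95, 2 * np.pi * 0.1
    coeffs = [-2 * r * np.cos(theta), r * r]
    x = ar_process(coeffs, 100_000, seed=7)
    model = et.burg_fit(x, 2)
    np.testing.assert_allclose(model.coefficients, coeffs, atol=0.02)


def test_burg_matches_yule_walker_on_long_stationary_data():
    x = ar_process([-1.0, 0.5], 200_000, seed=8)
    burg = et.burg_fit(x, 2)
    yw = et.yule_walker_fit(x, 2)
    np.testing.assert_allclose(burg.coefficients, yw.coefficients, rtol=0.01)


def test_burg_rejects_zero_energy():
    with pytest.raises(NumericalError):
        et.burg_fit(np.zeros(64), 2)


# ---------------------------------------------------------------------------
# AR PSD evaluation
# ---------------------------------------------------------------------------


def test_order_zero_model_gives_flat_spectrum():
    model = et.ARModel(order=0, coefficients=np.zeros(0), residual_power=3.5,
                       method="burg")
    psd = et.ar_psd(model, 1000.0, 65)
    np.testing.assert_allclose(psd.power, 3.5, rtol=1e-12)
    assert psd.frequencies[0] == 0.0
    assert psd.frequencies[-1] == 500.0


def test_psd_positive_and_peak_at_pole_angle():
    r, frac = 0.98, 0.23
    theta = 2 * np.pi * frac
    model = et.ARModel(
        order=2,
        coefficients=np.array([-2 * r * np.cos(theta), r * r]),
        residual_power=1.0,
        method="burg",
    )
    fs = 1.0
    psd = et.ar_psd(model, fs, 2049)
    assert np.all(psd.power > 0)
    assert np.all(np.isfinite(psd.power))
    peak = psd.frequencies[np.argmax(psd.power)]
    assert abs(peak - frac * fs) <= psd.grid_step


# ---------------------------------------------------------------------------
# Register zero-extension and segmentation
# ---------------------------------------------------------------------------


def test_zero_extension_arithmetic():
    samples = np.arange(1.0, 1001.0)
    win = et.RegisterWindow(samples=samples, window_index=0, pad_factor=4)
    ext = et.zero_extend_register(win)
    assert ext.size == 4000
    assert np.all(ext[:1500] == 0) and np.all(ext[-1500:] == 0)
    np.testing.assert_array_equal(ext[1500:2500], samples)


def test_zero_extension_identity_and_odd_split():
    samples = np.array([1.0, 2.0, 3.0])
    win1 = et.RegisterWindow(samples=samples, window_index=0, pad_factor=1)
    np.testing.assert_array_equal(et.zero_extend_register(win1), samples)
    # (pad-1)*Ni = 3 zeros: one leads, two trail
    win2 = et.RegisterWindow(samples=samples, window_index=0, pad_factor=2)
    ext = et.zero_extend_register(win2)
    np.testing.assert_array_equal(ext, [0.0, 1.0, 2.0, 3.0, 0.0, 0.0])


def test_zero_extension_refines_grid_step():
    """Padding by x multiplies the PSD grid density by x."""
    rng = np.random.default_rng(9)
    samples = rng.normal(size=1000)
    fs = 1e4
    psd1, _ = extended_burg_psd(samples, fs, pad_factor=1, order=8)
    psd4, _ = extended_burg_psd(samples, fs, pad_factor=4, order=8)
    assert psd1.grid_step == pytest.approx(fs / 1000)
    assert psd4.grid_step == pytest.approx(fs / 4000)


def test_memory_guard_refuses_oversized_register():
    win = et.RegisterWindow(samples=np.ones(1000), window_index=0, pad_factor=64)
    with pytest.raises(MemoryGuardError):
        et.zero_extend_register(win, max_samples=2**15)


def test_segmentation_partitions_the_span(small_pulse):
    field = et.RegularScattererField(mean_spacing=1.1e-3, count=24)
    trace = et.synthesize_regular_trace(small_pulse, field, 1540.0)
    windows = et.segment_trace(trace, 5, 200, pad_factor=2, sound_speed=1540.0)
    assert len(windows) == 5
    joined = np.concatenate([w.samples for w in windows])
    np.testing.assert_array_equal(joined, trace.samples[: 5 * 200])
    depths = np.array([w.start_depth for w in windows])
    np.testing.assert_allclose(
        np.diff(depths), 1540.0 * 200 / trace.sampling_rate / 2
    )
    with pytest.raises(ConfigurationError, match="at most"):
        et.segment_trace(trace, 1000, 200)


# ---------------------------------------------------------------------------
# Peak reading
# ---------------------------------------------------------------------------


def test_find_peak_and_tie_break():
    freqs = np.arange(0, 101, dtype=float)
    power = np.ones(101)
    power[40] = power[60] = 5.0  # two equal maxima
    psd = et.PSDEstimate(frequencies=freqs, power=power, grid_step=1.0,
                         source_length=200)
    assert et.find_peak_near(psd, 50.0, 30.0) == 40.0  # lower frequency wins
    assert et.find_peak_near(psd, 60.0, 5.0) == 60.0
    with pytest.raises(ConfigurationError):
        et.find_peak_near(psd, 500.0, 10.0)


def test_parabolic_refinement_stays_within_half_bin():
    freqs = np.arange(0, 101, dtype=float)
    power = np.exp(-0.5 * ((freqs - 50.3) / 2.0) ** 2)
    psd = et.PSDEstimate(frequencies=freqs, power=power, grid_step=1.0,
                         source_length=200)
    coarse = et.find_peak_near(psd, 50.0, 10.0)
    fine = et.find_peak_near(psd, 50.0, 10.0, refine=True)
    assert coarse == 50.0
    assert abs(fine - 50.3) < 0.05


# ---------------------------------------------------------------------------
# Comb spectra and cross-method oracles
# ---------------------------------------------------------------------------


def test_regular_trace_comb_peaks_at_resonance_multiples(comb_setup):
    """Noise-free regular trace: local PSD maxima within one grid step of
    every in-band multiple of v/(2d)."""
    thermal, pulse, field = comb_setup
    trace = et.synthesize_heated_trace(pulse, field, thermal, 0.0)
    order = suggest_ar_order(pulse.sampling_rate, thermal.fundamental, len(trace))
    psd, _ = extended_burg_psd(trace.samples, trace.sampling_rate,
                               pad_factor=4, order=order)
    f1 = thermal.fundamental
    for k in range(7, 14):  # lines within the 10 +- 3 MHz pulse band
        peak = et.find_peak_near(psd, k * f1, 0.45 * f1)
        assert abs(peak - k * f1) <= psd.grid_step, f"harmonic {k}"


def test_burg_peak_agrees_with_periodogram_on_sinusoids():
    fs = 10_000.0
    n = 8192
    t = np.arange(n) / fs
    rng = np.random.default_rng(10)
    x = (np.sin(2 * np.pi * 1234.0 * t) + 0.5 * np.sin(2 * np.pi * 2718.0 * t)
         + 0.05 * rng.normal(size=n))
    model = et.burg_fit(x, 8)
    psd = et.ar_psd(model, fs, n // 2 + 1)
    f_per, p_per = periodogram(x, fs=fs, nfft=n)
    burg_peak = psd.frequencies[np.argmax(psd.power)]
    per_peak = f_per[np.argmax(p_per)]
    assert abs(burg_peak - per_peak) <= psd.grid_step


def test_band_peak_stats_normalisation():
    freqs = np.linspace(0, 100, 101)
    power = np.ones(101)
    power[30] = 11.0
    psd = et.PSDEstimate(frequencies=freqs, power=power, grid_step=1.0,
                         source_length=200)
    peak, frac = band_peak_stats(psd, 20.0, 40.0)
    assert peak == 30.0
    assert frac == pytest.approx(11.0 / (20 + 11.0))


def test_suggested_order_spans_one_comb_period():
    order = suggest_ar_order(264e6, 700e3, 25_000)
    assert order >= 264e6 / 700e3  # at least one period of lag depth
    assert order <= 25_000 // 3
    # short registers clamp to Ni // 3
    assert suggest_ar_order(264e6, 700e3, 300) == 100
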