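"""High-resolution parametric (autoregressive) power-spectrum estimation.

The trace is modelled as white noise driving an all-pole filter
``1/A(z)``, ``A(z) = 1 + sum_k a_k z^-k``, so its PSD is
``sigma_w^2 / |A(f)|^2``.  Two fitting routes are provided:

* **Yule-Walker** -- solve the normal equations built from the biased
  sample autocorrelation (Levinson recursion via
  ``scipy.linalg.solve_toeplitz``).
* **Burg** -- minimise the summed forward and backward prediction-error
  power stage by stage under the Levinson-Durbin constraint.  The
  harmonic-mean denominator of the reflection-coefficient estimate
  guarantees ``|K_m| <= 1`` and hence a stable model.

Frequency resolution beyond ``fs / N`` is obtained by *register
zero-extension*: a short window of ``Ni`` samples is padded symmetrically
with zeros to ``Nf = pad_factor * Ni`` samples before fitting, and the AR
spectrum is evaluated on the ``fs / Nf`` grid.  Peak readings are
grid-quantised by default, mirroring the stepwise shifts such a grid
produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import ConfigurationError, MemoryGuardError, NumericalError
from .simulate import EchoTrace

#: Hard cap on the zero-extended register length (samples); beyond this the
#: extension is refused explicitly instead of silently truncated.
DEFAULT_MAX_REGISTER_SAMPLES = 2**24

#: Hard cap on the default AR order.
MAX_DEFAULT_ORDER = 1024

#: Default AR lag depth in units of the resonance period (in samples).
ORDER_PERIOD_FACTOR = 1.2


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ARModel:
    """All-pole model: ``x(n) = -sum a_k x(n-k) + w(n)``."""

    order: int
    coefficients: np.ndarray
    residual_power: float
    method: str
    reflection_coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (self.order,):
            raise ConfigurationError("coefficient length must equal order")
        if self.residual_power < 0:
            raise ConfigurationError("residual_power must be >= 0")
        object.__setattr__(self, "coefficients", coeffs)
        if self.reflection_coefficients is not None:
            object.__setattr__(
                self,
                "reflection_coefficients",
                np.asarray(self.reflection_coefficients, dtype=float),
            )

    def polynomial(self) -> np.ndarray:
        """``[1, a_1, ..., a_p]``."""
        return np.concatenate([[1.0], self.coefficients])

    def poles(self) -> np.ndarray:
        """Roots of ``A(z)`` in the z-plane (inside the unit circle if stable)."""
        return np.roots(self.polynomial())


@dataclass(frozen=True)
class PSDEstimate:
    """AR power spectrum on a uniform grid covering ``[0, fs/2]``."""

    frequencies: np.ndarray
    power: np.ndarray
    grid_step: float
    source_length: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ConfigurationError("frequency and power grids must match")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class RegisterWindow:
    """One fractional time-window of a trace, tagged for zero-extension."""

    samples: np.ndarray
    window_index: int
    pad_factor: int = 1
    start_depth: float = 0.0
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.pad_factor < 1:
            raise ConfigurationError("pad_factor must be >= 1")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def extended_length(self) -> int:
        return self.pad_factor * self.samples.size


# ---------------------------------------------------------------------------
# AR fitting
# ---------------------------------------------------------------------------


def yule_walker_fit(trace: np.ndarray, order: int) -> ARModel:
    """Fit an AR(p) model from the biased sample autocorrelation.

    The biased estimator (divide by N at every lag) keeps the Toeplitz
    system positive semidefinite.  Solved by Levinson recursion.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    if x.size <= order:
        raise ConfigurationError("trace length must exceed the AR order")
    if np.ptp(x) == 0:
        raise NumericalError("constant trace: autocorrelation system is singular")
    n = x.size
    # Biased autocorrelation for lags 0..p via FFT.
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: order + 1] / n
    if acf[0] == 0:
        raise NumericalError("zero-energy trace: autocorrelation is singular")
    try:
        a = scipy.linalg.solve_toeplitz((acf[:-1], acf[:-1]), -acf[1:])
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises rarely
        raise NumericalError("singular Yule-Walker system") from exc
    if not np.all(np.isfinite(a)):
        raise NumericalError("singular Yule-Walker system (non-finite solution)")
    sigma2 = float(acf[0] + np.dot(a, acf[1:]))
    return ARModel(
        order=order,
        coefficients=a,
        residual_power=max(sigma2, 0.0),
        method="yule_walker",
    )


def burg_fit(trace: np.ndarray, order: int) -> ARModel:
    """Fit an AR(p) model with Burg's lattice recursion.

    At each stage the reflection coefficient is the (negative) normalised
    cross-correlation of the forward and backward prediction errors; the
    coefficient vector is then updated through the Levinson-Durbin
    constraint and both error sequences are propagated one stage down the
    lattice.  The residual power is the driving-noise variance estimate,
    reduced by ``(1 - K_m^2)`` at every stage.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    if x.size <= order:
        raise ConfigurationError("trace length must exceed the AR order")
    f = x.copy()
    b = x.copy()
    a = np.zeros(0)
    energy = float(np.dot(x, x)) / x.size
    ks = np.empty(order)
    for m in range(order):
        fp = f[1:]
        bp = b[:-1]
        den = float(np.dot(fp, fp) + np.dot(bp, bp))
        if den == 0.0:
            raise NumericalError(
                f"zero prediction-error energy at Burg stage {m + 1}"
            )
        k = -2.0 * float(np.dot(fp, bp)) / den
        ks[m] = k
        a = np.concatenate([a + k * a[::-1], [k]])
        energy *= 1.0 - k * k
        f = fp + k * bp
        b = bp + k * fp
    return ARModel(
        order=order,
        coefficients=a,
        residual_power=max(energy, 0.0),
        method="burg",
        reflection_coefficients=ks,
    )


def ar_psd(model: ARModel, sampling_rate: float, n_freqs: int) -> PSDEstimate:
    """Evaluate ``residual_power / |A(f)|^2`` on ``n_freqs`` points in [0, fs/2].

    The grid step is ``fs / (2 (n_freqs - 1))``; choosing
    ``n_freqs = Nf // 2 + 1`` for an even register length ``Nf`` yields the
    canonical ``fs / Nf`` step of the zero-extension scheme.
    """
    if n_freqs < 2:
        raise ConfigurationError("n_freqs must be >= 2")
    if not sampling_rate > 0:
        raise ConfigurationError("sampling_rate must be positive")
    nfft = 2 * (n_freqs - 1)
    response = np.fft.rfft(model.polynomial(), nfft)
    power = model.residual_power / np.abs(response) ** 2
    freqs = np.arange(n_freqs) * (sampling_rate / nfft)
    return PSDEstimate(
        frequencies=freqs,
        power=power,
        grid_step=sampling_rate / nfft,
        source_length=nfft,
    )


# ---------------------------------------------------------------------------
# Register handling
# ---------------------------------------------------------------------------


def zero_extend_register(
    window: RegisterWindow, max_samples: int = DEFAULT_MAX_REGISTER_SAMPLES
) -> np.ndarray:
    """Symmetrically pad a window with zeros to ``Nf = pad_factor * Ni``.

    ``(pad_factor - 1) Ni / 2`` zeros go before and after the original
    samples; when that count is odd the extra zero goes at the tail.  The
    original samples are bit-identical in the middle of the result.
    """
    ni = window.samples.size
    nf = window.pad_factor * ni
    if nf > max_samples:
        raise MemoryGuardError(
            f"extended register of {nf} samples exceeds the cap of "
            f"{max_samples}; reduce pad_factor or raise max_samples"
        )
    total = nf - ni
    lead = total // 2
    tail = total - lead
    return np.concatenate([np.zeros(lead), window.samples, np.zeros(tail)])


def segment_trace(
    trace: EchoTrace,
    n_windows: int,
    window_length: int,
    pad_factor: int = 1,
    sound_speed: float = 1540.0,
    start_sample: int = 0,
) -> list[RegisterWindow]:
    """Cut a trace into contiguous, non-overlapping fractional windows.

    Each window is tagged with its start depth ``v t_start / 2``.
    """
    if n_windows < 1 or window_length < 1:
        raise ConfigurationError("n_windows and window_length must be >= 1")
    needed = start_sample + n_windows * window_length
    if needed > len(trace):
        feasible = (len(trace) - start_sample) // window_length
        raise ConfigurationError(
            f"trace of {len(trace)} samples supports at most {feasible} "
            f"windows of {window_length} samples (requested {n_windows})"
        )
    windows = []
    for j in range(n_windows):
        i0 = start_sample + j * window_length
        t_start = trace.start_time + i0 / trace.sampling_rate
        windows.append(
            RegisterWindow(
                samples=trace.samples[i0 : i0 + window_length],
                window_index=j,
                pad_factor=pad_factor,
                start_depth=sound_speed * t_start / 2.0,
                sampling_rate=trace.sampling_rate,
            )
        )
    return windows


def extended_burg_psd(
    samples: np.ndarray,
    sampling_rate: float,
    pad_factor: int = 1,
    order: int | None = None,
    max_samples: int = DEFAULT_MAX_REGISTER_SAMPLES,
) -> tuple[PSDEstimate, ARModel]:
    """Zero-extend a register, Burg-fit it, and evaluate the PSD on the
    ``fs / Nf`` grid -- the core high-resolution estimation step."""
    window = RegisterWindow(samples=samples, window_index=0, pad_factor=pad_factor,
                            sampling_rate=sampling_rate)
    extended = zero_extend_register(window, max_samples=max_samples)
    if order is None:
        order = min(MAX_DEFAULT_ORDER, max(2, window.samples.size // 4))
    model = burg_fit(extended, order)
    n_freqs = extended.size // 2 + 1
    psd = ar_psd(model, sampling_rate, n_freqs)
    return psd, model


def suggest_ar_order(
    sampling_rate: float, fundamental: float, n_samples: int
) -> int:
    """Default AR order for resonance-comb traces.

    A pulse train with fundamental ``f1`` repeats every ``fs / f1`` samples,
    and an all-pole model can only express that periodicity once its lag
    depth spans a full period (the ideal comb filter is ``1 - z**-P``).  The
    default is therefore ``1.2 * fs / f1`` -- one period plus margin for the
    non-integer period and the echo waveform -- capped at
    ``min(1024, Ni // 3)``.
    """
    if not sampling_rate > 0 or not fundamental > 0:
        raise ConfigurationError("sampling_rate and fundamental must be positive")
    order = int(np.ceil(ORDER_PERIOD_FACTOR * sampling_rate / fundamental))
    return int(np.clip(order, 2, min(MAX_DEFAULT_ORDER, max(2, n_samples // 3))))


# ---------------------------------------------------------------------------
# Peak reading
# ---------------------------------------------------------------------------


def find_peak_near(
    psd: PSDEstimate,
    expected: float,
    half_width: float,
    refine: bool = False,
) -> float:
    """Frequency of the strongest PSD sample within ``expected +- half_width``.

    Grid-quantised by default; ties break toward the lower frequency.  With
    ``refine=True`` a 3-point parabolic interpolation around the winning bin
    is applied instead.
    """
    mask = (psd.frequencies >= expected - half_width) & (
        psd.frequencies <= expected + half_width
    )
    if not np.any(mask):
        raise ConfigurationError(
            f"search band {expected:g} +- {half_width:g} Hz misses the grid"
        )
    idx = np.flatnonzero(mask)
    local = int(np.argmax(psd.power[idx]))
    i = idx[local]
    if not refine or i == 0 or i == psd.frequencies.size - 1:
        return float(psd.frequencies[i])
    p0, p1, p2 = psd.power[i - 1 : i + 2]
    denom = p0 - 2.0 * p1 + p2
    if denom == 0:
        return float(psd.frequencies[i])
    offset = 0.5 * (p0 - p2) / denom
    return float(psd.frequencies[i] + np.clip(offset, -0.5, 0.5) * psd.grid_step)


def band_peak_stats(
    psd: PSDEstimate, f_lo: float, f_hi: float
) -> tuple[float, float]:
    """(dominant peak frequency, peak power / total in-band power) for a band."""
    mask = (psd.frequencies >= f_lo) & (psd.frequencies <= f_hi)
    if not np.any(mask):
        raise ConfigurationError("band misses the PSD grid")
    idx = np.flatnonzero(mask)
    p = psd.power[idx]
    i = int(np.argmax(p))
    total = float(np.sum(p))
    if total == 0:
        raise NumericalError("zero in-band power")
    return float(psd.frequencies[idx[i]]), float(p[i] / total)
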