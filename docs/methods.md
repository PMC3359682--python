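# Methods

## Signal model

An A-scan from a scattering medium is modelled as a superposition of replicas
of the emitted pulse,

    s(t) = sum_m A_m P(t - t_m),        P(t) = -t exp(-4 w^2 t^2) sin(2 pi f0 t)  for t > 0,

with `f0` the transducer centre frequency and `w` its bandwidth, both plain
frequencies in Hz (no 2π inside the envelope exponent). The model assumes
far-field, attenuation-, dispersion- and diffraction-free propagation along a
one-dimensional path, so every echo keeps the emitted waveform exactly; only
the arrival times `t_m` carry information. Two scatterer geometries are
supported:

* **Regular lattice** — scatterer *m* at depth *m·d*, echo at `2 m d / v`.
* **Stochastic field** — inter-arrival times τ_m drawn i.i.d. from a gamma
  distribution parameterised by its mean and variance (method of moments:
  shape = mean²/var, scale = var/mean). Variance 0 degenerates to the
  regular case; a gamma with shape ≫ 1 is a quasi-regular lattice, shape ≤ 1
  a disordered or clustered one. Echo amplitudes default to 1 (regular) and
  i.i.d. uniform(0.5, 1.0) (stochastic); peak *locations*, not amplitudes,
  carry the thermometry signal, so the amplitude law is a free knob.

**Continuous-time evaluation is load-bearing.** Echo arrivals are never
rounded to the sample grid: the pulse is evaluated analytically at
`t_grid - t_m`. A 0.1 °C change moves each inter-arrival by ~40 ps, two
orders of magnitude below the sample period; snapping arrivals to samples
would erase the entire effect being measured.

## Thermal model

Temperature enters through two linear laws relative to the base temperature
T₀: spacing dilation `d(T) = d0 (1 + a dT)` and sound-speed drift
`v(T) = v0 + (dv/dT) dT`. The x-th overtone of the spacing resonance then
shifts, to first order, by

    df_x = (x / 2 d0) * k * dT,      k = dv/dT - a v0,

and the package inverts this law exactly to convert measured shifts to
temperature changes. For depth profiles, the medium is split into the
piecewise-constant segments of the imposed ΔT(z); each segment dilates and
propagates sound at its own temperature, and an echo's arrival time is twice
the sum of segment traversal times down to its scatterer. For uniform ΔT
this reproduces the exact overtone law identically (tested).

Defaults (all configurable):

| parameter | default | unit | why |
|---|---|---|---|
| v₀ | 1540 | m/s | canonical soft-tissue speed |
| α | 3.7 × 10⁻⁴ | 1/°C | water-like expansion |
| k | 0.44597 | (m/s)/°C | back-solved from the published 871.66 Hz / 0.1 °C displacement of the 43rd overtone at d₀ = 1.1 mm |
| dv/dT | k + α·v₀ ≈ 1.0158 | (m/s)/°C | makes the pair (α, dv/dT) consistent with k |
| sampling rate | 8 (f₀ + w) | Hz | comfortable Nyquist margin |
| pulse support | 2 / w | s | envelope decayed to ~10⁻⁷ |
| scatterers per trace | 64 | — | long enough for sharp comb lines, short enough for fast Burg fits |

`calibrate_effective_coefficient` exposes the back-solve so a user can
re-anchor k from any measured (ΔT, shift) pair. Note the published
displacement table is internally inconsistent at its 0.08 °C row (697.03 Hz
where the linear law calibrated from the 0.1 °C row gives 871.66 × 0.8 =
697.33 Hz); the package computes the law, not the misprint.

## High-resolution spectral estimation

The trace is modelled as white noise driving an all-pole filter; its PSD is
`E_p / |1 + sum a_k e^{-j 2 pi f k}|²`. Coefficients come from either the
Yule–Walker normal equations (biased autocorrelation, Levinson recursion —
the biased estimator keeps the Toeplitz system positive semidefinite) or,
preferentially, **Burg's lattice recursion**: at each stage the reflection
coefficient is the negative normalised cross-correlation of forward and
backward prediction errors, whose harmonic-mean denominator guarantees
|K_m| ≤ 1 and hence stability on any input; the coefficient vector is
updated through the Levinson–Durbin constraint.

**Register zero-extension.** A window of Nᵢ samples is padded symmetrically
with (pad_factor − 1)·Nᵢ/2 zeros on each side (odd totals put the extra zero
at the tail — a one-sample asymmetry cannot move a PSD magnitude peak), and
the Burg fit plus PSD evaluation run on the extended register, putting the
spectrum on the fs/Nf grid, Nf = pad_factor·Nᵢ. Since zeros contribute
nothing to the lattice inner products (up to edge terms of order p samples),
the fitted poles are essentially those of the raw window; the extension's
role is the refined evaluation grid. Registers beyond 2²⁴ samples are
refused with an explicit error rather than silently truncated.

**AR order.** A pulse train with fundamental f₁ repeats every P = fs/f₁
samples, and an all-pole model can only express that periodicity once its
lag depth spans a full period — the ideal comb filter is 1 − z⁻ᴾ. Orders
well below P (including the classical "two poles per spectral line" count)
leave the poles on broad band-shape features that do not move with
temperature. The default is therefore p = ⌈1.2 · fs/f₁⌉ (one period plus
margin for the non-integer period and the echo waveform), capped at
min(1024, Nᵢ/3). At the 30 MHz reference configuration this is p = 453 on a
~25 000-sample trace, which puts the baseline 43rd-overtone peak within one
grid bin of 30.1 MHz and tracks thermal shifts within one bin of the linear
law.

**Peak reading** is grid-quantised by default (the maximum bin in a search
band, ties broken toward the lower frequency); this reproduces the stepwise,
occasionally jumpy shift sequences such a grid produces, and surfaces the
quantisation in every estimate's `grid_step` field rather than smoothing it.
An optional three-point parabolic refinement exists behind a flag. Tracking
recentres the search band (half-width 0.45·f₁ — wide enough for thermal
drift, too narrow to hop overtones) on the previous peak, and declares a
peak lost if no bin in the band exceeds the in-band median power.

## The evaluation studies and their problem sizes

* **Resolution** — regular 1.1 mm lattice (f₁ = 700 kHz), 30 MHz / 3 MHz
  transducer (the bandwidth is a package choice; only the centre frequency
  is prescribed by the study design), 64 scatterers (~25 000 samples at
  264 MHz), zero-extended ×27 to a 393 Hz grid, order 453. Heating
  schedules: 30.1→30.6 °C in 0.1 °C steps, 30→30.6 °C in 0.08 °C steps,
  30→31 °C in 0.05 °C steps. Noise-free, fully deterministic. An optional
  multi-start mode re-runs a schedule at offset baseline temperatures and
  averages the measured mean shifts, smoothing grid-quantisation jumps.
* **Noise** — regular 5 mm lattice (f₁ = 154 kHz), 2 MHz / 1 MHz transducer,
  30–50 °C in 2 °C steps, white Gaussian noise calibrated to SNR ∈
  {1, 3, 6, 12, 30, 60, 120} dB against the mean-square trace power; the
  13th (2.0020 MHz) and 15th overtone bins are compared against the
  noise-free bins per temperature. Measured behaviour: bins are identical
  from 12 dB up; at 1–6 dB single-bin displacements appear, worth ~2 °C.
* **Variance** — stochastic fields, mean inter-arrival 800 ns, SD ∈
  {80 ns, 0.8 µs, 2.52 µs}, 10 MHz / 1.5 MHz transducer, 20 seeds per
  level; reports each seed's dominant in-band (f₀ ± 2w) peak and its power
  fraction (max bin / band total).

The study problem sizes above were chosen so a full acceptance run is a
few minutes of single-core compute while keeping every grid step at or
below the value each study's physics requires.

## What the synthetic data does and does not emulate

The generator reproduces the *geometry* of backscatter from semi-regular
media — echo timing, its thermal perturbation, timing disorder, and additive
electronic noise. It does not emulate frequency-dependent attenuation,
dispersion, diffraction, multiple scattering, speckle from unresolved
sub-wavelength scatterer populations, or transducer impulse-response
ripple. Passing tests therefore demonstrate the *estimator's* resolution and
robustness under the stated model, not performance on tissue; in real
echoes, attenuation tilts the usable band and unresolved speckle adds a
structured noise floor that this model represents only via its white-noise
channel.

A finding from the variance study worth stating plainly: at the 8th overtone
of an 800 ns inter-arrival process, a per-interval jitter of even 80 ns is
~5 rad of phase — the resonance comb is fully decohered in-band at all three
disorder levels, and the in-band spectrum is interference speckle shaped by
the pulse band. The mean dominant-peak location is then governed by the
pulse spectrum (≈ 9.9 MHz over seeds), and the dominant-peak power fraction
is *not* a monotone function of disorder: at SD = 2.52 µs (gamma shape
≈ 0.1) echoes cluster into near-coincident bursts whose spectrum approaches
the smooth unimodal pulse envelope, re-concentrating power. The
corresponding acceptance check asserts the monotone ordering anyway and is
expected to fail; the tables it is computed from are written unmodified.

## Numerical choices and degenerate inputs

* Burg residual power starts from the mean-square of the register and
  contracts by (1 − K_m²) per stage; a zero-energy register raises at the
  stage where the denominator vanishes. Constant traces are rejected by the
  Yule–Walker route explicitly.
* PSD grids are `n_freqs` uniform points on [0, fs/2] evaluated by rfft of
  the coefficient polynomial; `n_freqs = Nf/2 + 1` yields the canonical
  fs/Nf step.
* Trace durations are fixed per experiment (auto-sizing would give each
  temperature a different register length and hence a different grid).
  Stochastic durations reserve 6σ of slack on the total arrival spread; a
  seed exceeding it fails loudly with the required duration named.
* Windows are contiguous and non-overlapping; segmentation that does not fit
  the trace reports the maximum feasible window count.
* ΔT = 0 profiles, zero-variance fields, empty SNR lists and empty step
  schedules all reduce to their exact degenerate results and are tested.

## Known limitations

* The shift law is first-order; at |ΔT| of tens of °C the neglected
  ΔT² term (relative size ~αΔT) becomes visible next to a sub-0.1 °C
  resolution claim.
* Grid-quantised tracking makes per-step estimates multiples of the grid
  step; the temperature equivalent of one step (~0.045 °C at the reference
  configuration) is the true resolution floor, and occasional double-bin
  jumps appear when the true shift is a non-integer number of bins.
* The AR order rule assumes the register actually contains several periods
  of the resonance; windows shorter than ~3 periods clamp the order to
  Nᵢ/3 and lose the comb.
* Temperature is always relative (ΔT from T₀); absolute calibration of α
  and dv/dT separately is outside the package — only their combination k is
  observable.
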