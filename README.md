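# echotherm

Noninvasive ultrasonic tissue thermometry by high-resolution autoregressive
spectral tracking of scatterer-spacing resonance overtones.

## The problem

Soft tissues such as liver behave acoustically like a semi-regular lattice of
sub-wavelength scatterers with mean axial spacing *d*. A pulse-echo A-scan
through such a lattice is a train of pulse replicas whose mean inter-arrival
time 2*d*/*v* imprints a comb of resonances on the echo spectrum at

&nbsp;&nbsp;&nbsp;&nbsp;*f*<sub>x</sub> = *x* · *v*(*T*) / (2 *d*(*T*)),&nbsp;&nbsp;*x* = 1, 2, …

Heating the tissue dilates the lattice, *d*(*T*) = *d*₀(1 + α ΔT), and changes
the speed of sound, *v*(*T*) = *v*₀ + (d*v*/d*T*) ΔT, so every overtone shifts
linearly with temperature:

&nbsp;&nbsp;&nbsp;&nbsp;Δ*f*<sub>x</sub> = (*x* / 2*d*₀) · [d*v*/d*T* − α *v*₀] · ΔT.

Tracking a high overtone therefore turns a sub-millihertz-scale relative
frequency measurement into a tenth-of-a-degree temperature measurement — of
interest for hyperthermia monitoring and for early detection of the small
local temperature anomalies produced by inflammation or neovascularisation.
The catch is frequency resolution: resolving a ~900 Hz shift of a 30.1 MHz
peak needs a spectral grid of a few hundred hertz. `echotherm` gets there by

1. cutting the trace into fractional registers, zero-extending each register
   symmetrically from *N*ᵢ to *N*f = pad_factor × *N*ᵢ samples,
2. fitting an all-pole (autoregressive) model to the extended register with
   Burg's lattice recursion (Levinson–Durbin constrained, |*K*ₘ| ≤ 1, always
   stable), and
3. reading overtone peak locations off the resulting *f*ₛ/*N*f-step AR power
   spectrum and inverting the shift law above.

The package also contains the full synthetic-data machinery used to evaluate
the method: regular and gamma-jittered stochastic scatterer fields, a
parametric emitted pulse *P*(*t*) = −*t* e<sup>−4ω²t²</sup> sin(2π*f*₀*t*),
thermal perturbation of echo timing (uniform or depth-profiled), and
calibrated white-noise injection.

## Worked example

Track the 43rd overtone (30.1 MHz) of a 1.1 mm liver-like lattice through
noise-free heating from 30.1 °C to 30.6 °C in 0.1 °C steps:

```python
import echotherm as et

cfg = et.ExperimentConfig("resolution", steps_c=(0.1,))
res = et.run_resolution_experiment(cfg)
print(res.tables["resolution_summary"][
    ["step_c", "grid_step_hz", "theory_shift_hz",
     "mean_measured_shift_hz", "monotonic"]].to_string(index=False))
```

prints

```
 step_c  grid_step_hz  theory_shift_hz  mean_measured_shift_hz  monotonic
    0.1    393.235164           871.66               865.11736       True
```

Reading: the zero-extended Burg spectrum is evaluated on a 393 Hz grid; the
linear shift law predicts 871.66 Hz per 0.1 °C step (with the effective
thermal coefficient *k* = d*v*/d*T* − α*v*₀ ≈ 0.446 (m/s)/°C); the five
measured, grid-quantised peak displacements average 865.1 Hz — within one
grid step of the prediction — and the peak series is strictly monotonic, so
0.1 °C steps are cleanly resolved. Converting one grid step back through the
shift law, the temperature quantisation of this configuration is ≈ 0.045 °C.

The same machinery is exposed piecewise (`synthesize_heated_trace`,
`extended_burg_psd`, `track_harmonic`, `estimate_thermal_profile`, …) and via
a CLI:

```sh
echotherm simulate --model regular --f0 30e6 --bandwidth 3e6 \
    --spacing 1.1e-3 --delta-t 0.5 --out trace.txt
echotherm psd trace.txt --pad-factor 27 --order 453 --out psd.txt
echotherm experiment variance --seed 1 --out results/
```

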