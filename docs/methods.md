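# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ulfbis`. It is the package's own account of its science;
every empirical statement here is something the test suite or
`scripts/acceptance.py` actually computes.

## Measurement model

The virtual object is a fixed series loop: voltage generator → node 1 →
contact impedance Zin → node 2 → body Zbody → node 3 → contact Zout →
node 4 → reference resistor Rref → ground. General netlist simulation is
out of scope; only this four-node topology is supported.

* Zin, Zout: parallel RC, `1/(1/R + jωC)`.
* Zbody: Debye branch `R∞ + 1/(1/(R0−R∞) + jωC)`, i.e. the Cole–Cole
  model `R∞ + (R0−R∞)/(1+(jωτ)^a)` with `a = 1` and `τ = (R0−R∞)·C`.
* Nominal phantom: Rin = Rout = 100 kΩ, Cin = Cout = 100 µF, R∞ = 1 kΩ,
  R0−R∞ = 10 kΩ, C = 10 µF, Rref = 100 Ω; resistor tolerance 1 %,
  capacitor tolerance 5 %. Hence R0 = 11 kΩ and τ = 0.1 s.

Exact node phasors follow from the loop current
`I = v_gen / (Zin + Zbody + Zout + Rref)`; substituting them into the
extraction ratios recovers the closed-form impedances identically, which
serves as the pipeline's core oracle.

### Conventions

* Time dependence `e^{+jωt}`; capacitive reactance has negative imaginary
  part. All interfaces take ordinary frequency in Hz.
* `(jωτ)^a` uses the principal branch (standard Cole–Cole convention,
  continuous in `a` at 1).
* Signals are `V·cos(2πft − φ)`; the complex phasor is `u = V·e^{−jφ}` so
  that `Re{u·e^{jωt}}` reproduces the signal. The lock-in's quadrature
  reference is `−sin(2πft − φr)`, which orients the averaged products as
  `V̄X = ½VsVr·cos(φr−φs)`, `V̄Y = +½VsVr·sin(φr−φs)` and makes
  `φs = φr − atan2(V̄Y, V̄X)` and the complex form above mutually
  consistent. (With the opposite quadrature sign the recovered phasors are
  conjugated and the end-to-end identity fails near the relaxation corner
  — the closed-loop oracle pins the convention.)
* Generator phase is 0 at the first sample of every synthesized block.

## Waveform synthesis and the noise model

Each channel is the real part of its exact phasor times `e^{jωt}`, sampled
at `fs` for `round(n_periods·fs/f)` samples. Imperfections:

* **White noise**, independent per channel (models independent input
  amplifiers), RMS `white_rms` volts. Default 1.28·10⁻⁴ V: this places the
  per-bin amplitude floor of a 2¹⁷-sample rectangular-window FFT at
  ≈ −120 dB relative to a 0.5 V-peak carrier, the observed instrument
  floor. The hardware datasheet quantities (3.2 nV/√Hz input noise) do not
  determine the total channel noise — the measurement load dominates — so
  the total is a single free parameter fixed once here.
* **Pink fraction**: `pink_fraction` of `white_rms` is realized as
  1/f-shaped noise produced by a parallel bank of three first-order
  low-pass sections plus a direct path (Kellet's economy coefficients),
  renormalized to the requested RMS. The approximation holds over roughly
  four decades below Nyquist, which is ample for a per-point block.
* **Generator harmonics**: each (order h ≥ 2, level dB) entry re-solves
  the circuit at h·f with a scaled generator, so harmonics see the correct
  frequency-dependent transfer. Harmonics at or above Nyquist are skipped
  (the hardware's anti-alias stage would remove them). Default levels
  (−100 dB at 2f, −105 dB at 3f) give ≈ −100 dB THD. Because whole-period
  integration is orthogonal to integer harmonics, these do not bias the
  lock-in — a tested property.
* **Component tolerance**: `perturb_phantom` multiplies every resistance
  by (1+δ), δ ~ U(−r_tol, +r_tol), and every capacitance likewise with
  c_tol; deterministic given a seed. Nominal values are used everywhere
  unless a perturbed phantom is explicitly requested.

ADC quantization and inter-channel cross-talk are not modelled (32-bit
converters make the former negligible at these scales).

## Lock-in demodulation

Multiply the windowed channel by the cosine and (negated) sine references,
average over the largest whole number of excitation periods that fit —
periods are counted in time, so fractional samples-per-period ratios are
allowed and leftover samples are discarded — then convert to amplitude and
phase. With an integer number of samples per period the double-frequency
mixing term sums to zero exactly and recovery is at machine precision; in
general the truncation residual is O(1/n).

The optional RC low-pass after the mixers is the backward-Euler
discretization `y[k] = y[k−1] + α(x[k] − y[k−1])`, `α = dt/(RC+dt)`,
`RC = 1/(2π·cutoff)`, DC gain exactly 1; order 2 cascades two sections.
Inside `demodulate` the filter state is initialized at the whole-period
mean of the mixer product, so the settling transient does not bias short
simulated records; with that choice, integration with the filter engaged
agrees with plain integration to 0.1 % at ≥ 100 periods (tested), the
software analogue of the statement that the low-pass is redundant when
whole-period integration is used. The optional pre-mixer band-pass is a
first-order complementary high-pass ∘ low-pass pair half a decade either
side of the reference; its exact hardware topology is not specified, this
composition is the package's choice, and it defaults to off. The hardware's
second band-pass (a delay-matching trick between two physical paths) has no
software analogue and is deliberately not implemented.

The FFT mode returns a single-sided amplitude spectrum normalized (with
window coherent-gain correction) so a full-scale sinusoid at a bin center
reads its peak amplitude; used to characterize noise floors.

## Sweep profiles

Grids are log-equidistant, `f_min·10^(k/N)`, half-open `[f_min, f_max)` —
including both endpoints would give 8N+1 points over eight decades instead
of the protocol's 8N (40/80/264 at N = 5/10/33).

* **paper profile**: fs = 375 kS/s above 10 kHz, 37.5 kS/s below. Dwell
  times per decade (at 33 points/decade): 18000 s, 1800 s, 180 s, 40 s for
  the four decades below 10 Hz, and 33 s for each decade of 10 Hz–100 kHz
  (the quoted 132 s for that four-decade span is split equally — the
  apportioning is not stated and this is the package's assumption). For
  other densities the per-point dwell scales by 33/N, preserving total
  decade time; counts are rounded to whole periods, minimum one.
* **fast profile**: sample rate = paper rate capped at 2000 samples per
  period and floored at 16 per period (the floor overrides the paper cap
  above ≈ 23 kHz, where the two rules conflict), then snapped to an
  integer samples-per-period count. Coherent sampling makes the
  whole-period sums exact, so the noiseless pipeline recovers phasors at
  machine precision rather than the O(1/n) of fractional truncation —
  with only 8 integration periods per point (the fast default) the
  fractional-period residual would otherwise reach the percent level at
  high frequencies. Integration is a fixed, configurable 8 periods.

Per-point noise sub-seeds are `master_seed + k`, making sweeps
deterministic and execution-order independent; repeated sweeps use master
seeds `base + 1000·r` (plans never exceed 1000 points). The simulated
problem sizes — 40-point grids, 8 periods/point, ≤ 2000 samples/period —
are the package's default study conditions; the paper profile with its
full dwell times remains available through configuration.

## Extraction, averaging, errors

Extraction applies the four ratio formulas directly in complex arithmetic;
`Z'` is computed as the sum of the three parts so additivity is exact in
floating point. `u4 = 0` (no loop current) is a degenerate-measurement
error. Averaging of repeats is the complex mean per frequency and channel,
requiring identical grids. Relative errors are
`100·|Z′ − Z|/|Z|` per channel against the closed-form phantom values.

## Cole–Cole fitting

Levenberg–Marquardt (MINPACK via lmfit) on residuals stacked over real and
imaginary parts — the standard complex-NLLS reading; a magnitude-only mode
exists behind a flag for sensitivity analysis. Parameterization: `R∞ > 0`,
increment `ΔR = R0 − R∞ > 0`, `τ > 0`, `a ∈ (10⁻³, 1]`; bounds are
enforced by lmfit's smooth internal parameter transform, keeping the
optimizer well-behaved at the `a = 1` boundary where the phantom truth
lies. Consequently, when noise would push the unconstrained optimum above
1, the estimator returns exactly `a = 1` — the exponent error can be
identically zero on some seeds.

Initialization is data-driven: `R∞⁰ = |Z|` at the highest frequency,
`R0⁰ = |Z|` at the lowest, `τ⁰ = 1/(2πf*)` with `f*` the frequency of
maximal |Im Z| (geometric mid-frequency if the spectrum is purely real),
`a⁰ = 0.9`. Solver tolerances are tight (xtol = ftol = 10⁻¹⁴) so the
noiseless Debye fit recovers all four parameters to better than 0.01 %.
Flat spectra and solver failures return a flagged, non-converged result
rather than raising. `R²` uses the stacked real/imaginary residual and
total sums with the complex mean — equivalent to magnitudes of complex
differences; whether the original analysis stacked components or used
magnitudes is not stated, stacking is this package's documented choice.

## What the synthetic data does and does not show

The generator reproduces: exact steady-state circuit behaviour, the
instrument's sampling rates, whole-period integration, a flat noise floor
at the observed level with a 1/f admixture, generator harmonics with
correct circuit transfer, and component tolerances. It does not reproduce:
electrode polarization drift, temperature drift over the multi-hour
ultra-low-frequency sweeps, amplifier 1/f corner details, settling
transients after frequency switching (synthesis is steady-state by
construction), or cross-talk. Passing tests therefore demonstrate the
correctness and noise-robustness of the *evaluation method* — residual
rejection, demodulation precision, fit accuracy — not the behaviour of any
physical electrode–tissue interface. In particular, noisy-simulation
parameter errors (ϵ ≲ 0.3 %) are smaller than the physically measured ones
(ϵa up to ≈ 3 %), which include effects the noise model deliberately
omits; they sit on the correct side of the published tolerance bounds.

## Degenerate inputs and edge cases

* f = 0 is a valid frequency for all circuit models (DC limits).
* Demodulation requires ≥ 1 whole period and a reference frequency equal
  to the block's excitation frequency (relative tolerance 10⁻¹²).
* Nyquist violations in synthesis or planning raise input errors.
* `points_per_decade` outside [3, 100] is rejected, matching the
  instrument's range.

## Limitations

* Only voltage-generator excitation is implemented (the method also admits
  current excitation; not validated here).
* Single-dispersion fitting only; no sums of Cole–Cole terms.
* No real-time/streaming operation; the dual-microcontroller task split of
  the hardware is irrelevant to the simulation and not modelled.
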