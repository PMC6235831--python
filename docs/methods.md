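# Methods

`synaptrain` analyses evoked-EPSC sweep recordings from large facilitating
synapses (the hippocampal mossy-fiber → CA3 connection is the motivating
case) and ships a stochastic generator that emulates the three experimental
conditions its presets are named after: a quantal-regime recording under
partial Ca²⁺-channel block (`Cd`), a wild-type facilitating bouton (`WT`)
and a synaptotagmin-7-depleted variant with weakened facilitation and slowed
vesicle resupply (`PSKO`).

## Quantal model

For a bouton with `N` equivalent release sites, sparse release decomposes
the per-stimulus success probability into single- and two-site events
(higher orders are negligible at these rates):

```
p_tot = N·P(s) + C(N,2)·P(s+s),   P(s+s) = P(s)²
⇒  C(N,2)·x² + N·x − p_tot = 0,   x = P(s)
```

The positive root is the per-site release probability; the bi-quantal
contamination — the fraction of apparent single-vesicle events that are
two-site coincidences — is `C(N,2)·P(s+s)/(N·P(s)) = (N−1)·x/2`.

Two modes are exposed. `solve_release_quadratic` is exact algebra.
`rounded_contamination` reproduces the printed-arithmetic convention in
which the positive root is rounded to two significant figures before
back-substitution (`P(s+s) = (p_tot − N·x)/C(N,2)`); for
`p_tot = 0.12, N = 20` the rounded chain gives `P(s+s) = 3.16e-5` and a
contamination of 5.26%, whereas exact algebra gives `3.24e-5` and 5.41%.
Both are deliberately available because the rounded chain is what the
two-significant-figure convention produces, while the exact mode is
internally consistent; exact is the default. `N` is a parameter everywhere
(20 is an assumption about mossy-fiber boutons, not a measurement).

## Synthetic-data generator

An event-driven model evaluated at stimulus times only (all observables are
per-stimulus, so nothing is gained by continuous integration):

* a pool of `M` docked vesicles, full at sweep start;
* per stimulus `i`, each docked vesicle releases independently with
  probability `min(1, p0·F_i)`, where
  `F_i = 1 + a·Σ_{j<i} exp(−(t_i−t_j)/τ_F)` is a phenomenological
  residual-Ca²⁺/facilitation variable;
* between stimuli each empty slot refills with probability
  `1 − exp(−r·Δt)`;
* each released vesicle contributes an i.i.d. gamma(k, θ) amplitude;
  Gaussian baseline noise (SD `noise_sd_pA`) is added to the measured sweep
  amplitude, clipped at zero (amplitudes are magnitudes);
* sweeps are independent (the inter-sweep interval is metadata only; slow
  cross-sweep facilitation at ~1 Hz is not modelled, so the simulated
  0.1 Hz → 1 Hz frequency-facilitation ratio is 1 in both genotypes).

One `numpy` generator drives a whole simulation, stimulus-major and
vectorized across sweeps; results are bit-reproducible from
`(params, protocol, n_sweeps, seed)`.

### Quantal amplitude calibration

Measured "quantal" amplitudes in the Cd regime are success amplitudes, and
~5–6% of successes are two-site events. The single-vesicle gamma is
therefore calibrated so that the *success mixture* — gamma(k·R, θ) weighted
by the binomial release count R conditioned on R ≥ 1 — has mean 42.4 pA and
median 38.0 pA, the measured success statistics. This yields k ≈ 3.91,
θ ≈ 10.21 pA and a single-vesicle mean of ≈ 39.9 pA. A deliberate
consequence: converting train slopes with the measured quantal size
(42.4 pA), as the cumulative-amplitude method prescribes, carries the
method's intrinsic ≈ −6% bias, which the recovery tests absorb inside their
±10% band.

### Preset constants

Pinned by measured values:

| quantity | value | used by |
|---|---|---|
| release sites N | 20 | quantal model, all presets |
| Cd failure rate | 88% → p0 = 1 − 0.88^(1/20) ≈ 0.00637 | `Cd` |
| success mean / median | 42.4 / 38.0 pA | gamma calibration |
| steady resupply at 20 Hz | 13 (WT), 7 (PSKO) SV per 50 ms | refill calibration |
| transmission fraction at stimulus 15 | 0.63 (WT), 0.45 (PSKO) | spike calibration |

Free design constants (train shapes are only available graphically, so
these are the package's own choices):

* `M = 300` docked vesicles (15 per site), `p0 = 0.015`. Mossy-fiber
  boutons carry very large vesicle pools; a large pool with a low basal
  release probability places mid-train stimuli in a depletion *transient*,
  reproducing the rise–peak–decline train envelope and giving the
  facilitation increment real leverage over mid-train amplitudes. Basal
  first-pulse response ≈ 180 pA with a ~1% failure rate at 0.1 Hz.
* `a_WT = 1.0`, `τ_F = 0.4 s`: strong train facilitation at 20–40 Hz,
  paired-pulse ratio ≈ 1.9 at 40 ms, negligible facilitation at 1 Hz.
* `noise_sd_pA = 3.5`: typical whole-cell baseline noise; the default
  failure threshold (3 × SD = 10.5 pA) misclassifies < 3% of successes.
* Spike stage: leaky integrator, `τ_m = 0.35 s` (an effective integration
  constant for sustained train depolarization, longer than a membrane time
  constant), weight 1 (V in pA-equivalents), reset to 0 after a spike, and
  per-stimulus membrane noise SD 100 pA-equivalents representing background
  synaptic bombardment. The noise matters: with a hard deterministic
  threshold the fraction-vs-amplitude relation is too steep to yield 0.63
  and 0.45 under a single frozen threshold.

Calibration-derived entries are frozen in `synaptrain.presets` and marked
`CAL`; each is reproducible from its target via the `calibrate_*` routines
(bisection with common random numbers, deterministic given a seed):

* `refill_rate`: bisection until the mean vesicles released per stimulus
  over the last half of a 100-stimulus train at the protocol frequency
  matches the resupply target (relative tolerance 2% by default).
* `threshold`: bisection on a single large simulated sweep set until the
  transmission fraction at the target stimulus matches (WT, stimulus 15,
  0.63); the WT threshold is then frozen and reused for PSKO.
* `facil_increment` (PSKO): outer bisection on `a` against the 0.45
  transmission target under the frozen threshold, with the refill rate
  re-calibrated to 7 SV/ISI at every step (the two parameters are coupled
  through pool occupancy). Result: a ≈ 0.48, about half the WT increment.

## Analysis conventions

* **Failure classification**: amplitude below a threshold; default
  3 × baseline-noise SD (the criterion used in the original recordings is
  not documented, so this conventional detection limit is the package's
  stand-in), overridable as an absolute pA value.
* **Facilitation curves**: per unit (neuron), per-stimulus column means are
  normalized by that unit's first-stimulus mean; curves are then averaged
  across units with SEM (means-of-columns-then-ratio, never mean of
  per-sweep ratios — pinned by a fixture test). The per-neuron-then-across
  order is a documented choice, not an attributed one.
* **Replenishment**: OLS on the cumulative mean-amplitude curve over the
  fit window; `"auto"` = second half of the train (stimuli ⌈n/2⌉+1…n,
  i.e. 51–100 for 100-stimulus trains), a symmetric parameter-free default
  since "the late linear segment" is not otherwise defined. r² < 0.9 under
  the auto window raises a warning (steady state not reached) but the fit
  is returned. Rates are reported per inter-stimulus interval and per
  second to stay comparable across 20/40 Hz protocols.
* **Group statistics**: D'Agostino–Pearson normality per group, then
  two-sided t-test (both normal) or Mann–Whitney (otherwise); groups under
  8 observations fall back to the rank test with a warning. Curve-level
  comparisons are a split-plot design: group is a between-unit factor and
  must be tested against unit-to-unit variation (equivalently, one-way
  ANOVA on per-unit curve means). Testing it against the pooled cell
  residual looks like the obvious two-way ANOVA but is strongly
  anticonservative under within-unit correlation — a null simulation puts
  its false-positive rate near 45% at α = 0.05 — so the split-plot form is
  used.

## What the generator does and does not emulate

It reproduces per-stimulus amplitude statistics: failure rates, quantal
mixtures, facilitation envelopes, depletion transients, steady-state
resupply and probabilistic spike transmission, with realistic sweep-level
variability. It does not model raw 10 kHz traces (no kinetics, rise/decay
times or peak detection), calcium-channel or Syt7 molecular dynamics,
heterogeneous release sites, cross-sweep (slow) facilitation, or a
conductance-based postsynaptic neuron. Tests passing on simulated data
therefore validate the estimators' statistical behaviour under the model's
assumptions — they do not certify performance on raw-trace artefacts such
as imperfect baselining or amplitude-measurement error.

## Numerical choices and degenerate inputs

Quadratic roots come from the closed form (discriminant ≥ N² > 0 always);
`p_tot = 0` returns a zero root and zero contamination in exact mode and is
a degenerate-input error in rounded mode (the ratio is undefined).
Release probabilities exceeding 1 after facilitation are clamped and
logged, never an error. Bisection calibrators reuse one seed schedule per
search (common random numbers) so responses are monotone step functions and
the results deterministic; unattainable targets raise a calibration error
carrying the search bracket. Empty recordings round-trip through CSV;
zero-success quantal samples, zero first-pulse baselines and ragged curve
inputs raise typed errors rather than propagating NaNs.

## Test and verification sizes

The verification experiments use 2000-trial quantal runs (five replicates
averaged where a ±3% check would otherwise sit at ~1 sampling SD),
20 neurons × 20 sweeps × 100 stimuli for replenishment recovery (also at
true rates 4, 7, 10, 13 SV/ISI), and 16 units × 5 sweeps × 30 stimuli for
spike transmission with 20 replicate experiments averaged (one such
experiment has SE ≈ 0.054 on a fraction near 0.5, so a single replicate
cannot support a ±0.02 check). The type-I-error property of the gated
comparison uses 1000 Gaussian-null simulations.

## Known limitations

* The replenishment estimate inherits the −6% quantal-size conversion bias
  described above; it is reported as-is because the conversion by the
  measured quantal size is part of the method.
* The spike stage is phenomenological; its threshold, integration constant
  and noise have no direct biophysical counterparts and only the calibrated
  operating points are meaningful.
* The equal-release-site assumption is taken as given; no heterogeneous-p
  extension, no variance-mean analysis, and no release-site-number
  inference.
* Facilitation parameters (a, τ_F) are qualitative: they are constrained
  only by calibration targets and orderings, not by measured time courses.
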