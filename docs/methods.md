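# Methods

## Polymer models and unit conversions

Double-stranded DNA follows the extensible worm-like chain,
`x/Lc = 1 − ½√(kBT/(F·Lp)) + F/S`, with defaults `Lp = 51.1 nm`,
`S = 1006 pN`, helical rise `0.34 nm/bp`, and `kBT = 4.089 pN·nm`
(k_B·296.15 K, i.e. 23 °C; all defaults overridable through
`DsWlcParams`). The model diverges at F = 0 and the entropic term
dominates below ~0.5 pN, so the pipeline performs bp conversions only at
forces ≥ 0.5 pN; the trace generators clamp the relative extension at 0
below that. At the 17 pN reference force the extension per base pair is
0.334 nm/bp (0.33 to two decimals), the factor used to convert telomere
extensions to lengths. The helical rise of 0.34 nm/bp is the canonical
B-DNA value; it is required to reproduce that factor and is the value
consistent with the conversions used throughout.

Single-stranded DNA follows the Marko–Siggia interpolation
`F = kBT/Lp·(¼(1−r)⁻² + r − ¼)` with `Lp = 0.87 nm` and
`0.69 nm/nt`, appropriate for ~100 mM NaCl. Its numeric inverse is a
bracketed Brent solve on r ∈ [0, 1) to 1e−9 absolute tolerance
(monotonicity guarantees uniqueness).

Rupture leaps (ΔL) are converted to bp with the force-dependent factor
`rise · x_rel(F_test)` at the test force where the leap is scored —
not a fixed 0.33 nm/bp — because test forces span 2–20 pN and the
relative extension varies appreciably over that range. This is the
dimensionally consistent choice; whether a fixed factor was ever
applied instead is not decidable from descriptions of such assays, and
the difference is up to ~25% at 2 pN.

## Synthetic trace generator

The generator emulates a magnetic-tweezers instrument sampling at
≥100 Hz with Gaussian bead noise. The noise SD defaults to a
force-dependent ramp — 8 nm at ≤8 pN falling linearly to 3 nm at
≥14 pN — reflecting the smaller Brownian bead excursions of a taut
tether; the values were chosen once so that ~10-bp unzipping steps are
resolvable at 100 Hz after step fitting, and are configurable. Telomere
lengths are drawn from N(2.5, 0.9) kb truncated to [0.3, 7.4] kb.
Force jumps are rendered as 390 ms linear ramps (the measured
force-change time of the emulated instrument class), not as
discontinuities.

* **Force ramp / force jump.** Extension is the WLC prediction for the
  currently released length `(TL − Σ compacted ΔL)·rise·x_rel(F)` plus
  noise. Under a ramp, loop ruptures are drawn by inverse-CDF sampling
  of the integrated Bell–Evans hazard along the force trajectory; at a
  constant test force, bound loops rupture sequentially with
  exponential waiting times of rate `k(F_test)` (so recorded dwells are
  exponential by construction), and anything still bound at the jump to
  the high force is released there. Per-cycle binding probabilities
  default to the observed 38/50/76/60% at 10/20/25/40 nM, exposed as a
  lookup table.
* **Strand separation.** The long hairpin stem is 18 bp of fork-side
  random sequence, 10 TTAGGG repeats, TGG, 10 repeats, CGTC, 3 repeats,
  and 6 bp of loop-side filler — 169 bp total, spacer first bases at
  stem positions 79 and 142 (1-based from the fork end in unzipping
  order). The short construct keeps 13 repeats on the same scaffold;
  its internal filler length is configurable since only its repeat
  count is constrained. The 18-bp fork sequence and 6-bp filler are
  synthetic stand-in sequences (any non-telomeric sequence serves).
  A TRF1 dimer occupies two adjacent repeats (12 bp); footprints must
  not overlap each other or the spacers. At F_test the fork advances
  instantly between blocks, pauses an exponential dwell at each bound
  dimer, and each unzipped bp releases 2 nt of ssDNA (both strands join
  the tether). Backward fork excursions are generated only when F_test
  is within 0.9 pN of the 15.1 pN critical melting force, mimicking the
  observed force sensitivity of hopping; the threshold is configurable.
* **Hopping.** A two-state telegraph process with rates
  `k_f = a·e^{+δ/2}`, `k_b = a·e^{−δ/2}`, `δ = (F − F½)Δx/kBT`, so that
  detailed balance gives the Boltzmann open probability exactly. The
  attempt rate `a` (dwell scale at F½) defaults to 1 s⁻¹, matching
  second-scale fork dwells. Traces shorter than 20 expected dwells are
  flagged in metadata, and parameter combinations whose mean dwell is
  below 5 samples are rejected.
* **Loop populations.** ΔL values are drawn from per-condition Gaussian
  mixtures (presets tabulated per TRF1 concentration and TL bin);
  draws are rejected when the running sum would exceed the telomere
  length. This shared-budget rejection is the mechanism that induces
  the negative N–ΔL correlation in the synthetic ensembles; the
  mixture weights within a preset are equal because only component
  centers and widths are constrained. The Poisson mean of binding
  attempts per molecule (default 6–8 in the analyses) sets how strongly
  the budget binds.

All generators require an explicit integer seed and are bit-reproducible
given (seed, parameters). What the generator does **not** emulate:
instrument drift, camera/tracking artifacts, bead rotation, force
calibration error, non-exponential (multi-state) unbinding, and
sequence-dependent unzipping free energies. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
stochastic models, not robustness to those instrument systematics.

## Step fitting

Greedy recursive change-point search: repeatedly split the plateau
whose best single split maximally reduces the SSE (prefix-sum
evaluation, ties to the earlier index). Stopping uses a Schwarz-type
significance penalty: a step is accepted while its SSE reduction
exceeds `penalty_factor·σ̂²·log n` (default factor 3), with σ̂ the
median-absolute-first-difference noise estimate. A counter-fit quality
ratio (total SSE of midpoint-placed steps over the fitted steps) was
evaluated as the stopping rule first, but the ratio is ≥ 1 by
construction — the optimally placed split always beats the midpoint —
so no fixed threshold near 1 can both detect low-prominence steps and
stop on pure noise; the penalized rule handles both and reduces to
exact recovery on noiseless staircases (σ̂ = 0). After selection, each
change point is locally re-optimised between its neighbours
(coordinate descent), which removes the greedy sequence's occasional
misplacements; on noiseless staircases of ≤4 steps the result equals
the exact dynamic-programming optimum. Plateaus closer than
`merge_factor·σ̂` (default 1; 3 in rupture extraction, where leaps
dwarf the noise) are merged, and plateaus at or below the 20 ms
Nyquist dwell floor (two samples at 100 Hz) are absorbed into the
nearer-level neighbour. Sub-step dwells are the durations of the
preceding plateau; the first dwell in a window is counted from the
window start (the transit to the first pause is treated as
instantaneous at the sampling resolution), and the 390 ms jump
transition is excluded from the scoring window.

## Zero correction and residence maps

A strand-separation trace is re-referenced by the extension of the
fully open hairpin at F_test (the highest sustained plateau of the
first F_test hold); corrected values are
`(open − extension)/(2 nt/bp · ss nm/nt at F_test)` — base pairs still
to unzip, 0 when open, the stem length when closed. Residence maps
accumulate each step-fitted plateau's dwell into the 1-bp bin of its
fork position (`stem − level + 1`, the first still-closed base pair);
plateaus within 2 bp of the open level are excluded because the open
state's dwell is not fork residence. Bound dimers sit only on intact
tandem repeats, so the spacer windows [79–81] and [142–145] — and the
11 bp upstream of each spacer, where no 12-bp footprint fits — carry
near-zero occupancy and appear as valleys against the flanking
footprint peaks. Plateau-position noise (~1–2 bp for short pauses at
3 nm bead noise) leaks small mass into bins adjacent to true pause
sites, which is why valley checks compare window densities against
flanking peaks rather than requiring exact zeros.

## Hidden Markov analysis and energetics

The two-state Gaussian HMM (shared emission variance) is fitted by
Baum–Welch with k-means initialisation and 5 random restarts (seeded;
best likelihood kept), tolerance 1e−6 on the log-likelihood, ≤500
iterations; states are decoded by the Viterbi path, and the forward
state is the one with the larger mean extension. Dwells are decoded
run lengths over the sampling rate; dwells truncated by the trace
boundaries are excluded, which ignores right-censoring and biases mean
dwells slightly downward when dwells approach the trace length — the
analyses use holds ≥100 expected dwells long, where the effect is
negligible. Dwells at or below 20 ms are discarded (Nyquist floor).

The open probability is the forward-state time fraction with a
binomial-style SE whose effective n is the decoded dwell count (samples
within a dwell are not independent). The Boltzmann relation is fitted
by weighted nonlinear least squares as
`P_o(F) = 1/(1 + exp((F½ − F)·Δx/kBT))`; the exponent carries an
explicit /kBT — statements of this relation that omit it are
dimensionally inconsistent, and the implementation always divides by
kBT. `ΔG = F½·Δx/kBT` is reported in kBT units at 23 °C. For the
two-condition energetics replica the presets are ΔG = 61 and 50 kBT at
F½ = 14.7 pN; the per-condition Δx values (17.0 and 13.9 nm) are
back-calculated from those, since only ΔG and F½ are constrained.

## Kinetic and statistical fits

* **Bell–Evans:** least squares of `ln(1/⟨τ⟩)` on F (slope `x†/kBT`,
  intercept `ln k0`), unweighted by default with a weighted variant
  accepting user SEs. The extrapolated zero-force dwell is reported as
  `1/k0` — note that a 0.04 s⁻¹ rate corresponds to 25 s, not 23 s;
  quoted pairs that disagree with `1/k0` are not reproduced.
* **Exponential dwells:** the point estimate is the left-truncated MLE
  `τ̂ = mean(d − floor)` for the 20 ms dwell floor; a decaying-
  exponential histogram fit and its R² are reported alongside for
  comparability with histogram-based analyses. SE is `τ̂/√n`.
* **Hill:** `f = Cⁿ/(K_dⁿ + Cⁿ)` by nonlinear least squares; n floats
  by default (the printed fits do not constrain it) with an option to
  fix n = 1.
* **Gaussian mixtures:** scikit-learn EM with 10 seeded restarts;
  component count by BIC over 1–4 when not fixed.
* **Partial correlations:** the first-order recursion
  `r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`, applied
  recursively for second order; verified against the
  residual-regression identity and an independent implementation in the
  test suite. p-values are two-sided from t with `n − 2 − order` df; no
  multiple-testing correction (single-test reporting).

## Problem sizes

The analyses and acceptance script run at desk scale on one CPU:
200 force-ramp molecules for the TL distribution; 200 rupture dwells
per force at F = 2–8 pN for Bell–Evans recovery (dwell-level
simulation; the full trace → step-fit → rupture pipeline is exercised
at ~150 events in the integration analyses); 1290 and 588 pause dwells
for the two τ recoveries; 500 ΔL draws for the mixture; 131 molecules
(~900 events) for the correlation; and, for the hopping energetics, 20
forces per condition spanning F½ ± 0.6 pN with 1000 s holds at 100 Hz,
giving ~1000 dwells per force — the dwell count, not the sampling rate,
sets the precision of each open probability, and this size puts the
ΔΔG standard error near 1 kBT. The full acceptance run takes about two
minutes.

## Known limitations

Two-state models only (no ≥3-state HMMs or model selection over state
number); no drift or Allan-variance noise modelling; no
Dudko–Hummer–Szabo force-spectroscopy corrections; right-censored
dwells discarded rather than modelled; the synthetic hairpin's
non-repeat sequences are stand-ins, so sequence-specific unzipping
energetics are out of scope; salt dependence of the polymer parameters
is not modelled (all defaults are for ~100 mM NaCl).
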