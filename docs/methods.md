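# Methods

## Scope and model

`avakit` analyzes spontaneous population activity recorded with
two-photon calcium imaging at cellular resolution: a field of roughly
80 neurons sampled at 15 Hz for 5000 frames per movie. The pipeline
takes ΔF/F traces (or precomputed spike-rate rasters), estimates a
per-neuron per-frame spike rate λ, and quantifies how activity
propagates through the population: pairwise synchrony, neuronal
avalanches, branching parameters, and single-neuron burst persistence.

The organizing framework is the critical branching process. Activity at
frame *t* is treated as ancestors whose descendants appear at *t* + 1;
the branching parameter σ (descendant activity over ancestor activity)
is 1 at criticality, where avalanche sizes follow a power law
P(s) ∝ s^−τ with the mean-field exponent τ = 3/2 and mean size grows
with duration as ⟨s⟩(T) ∝ T^χ with χ = 2.

## Synthetic data generator

`synth.simulate_branching_raster` draws a driven branching process on
the frame grid:

- Poisson(`drive_rate`) spontaneous seed activations per frame, placed
  uniformly;
- each cascade-activated neuron at *t* spawns Poisson(`offspring_mean`)
  activations at *t* + 1, targets uniform with replacement
  (self-excitation allowed, so the Galton–Watson offspring law is exact
  and closed-form oracles apply);
- each active neuron independently stays active at *t* + 1 with
  probability `persist_prob`. Persistence-only continuations do **not**
  spawn offspring: they model passive single-neuron burst prolongation
  superimposed on the cascade. This is what lets persistence raise
  *repeat* activations and burst lengths without recruiting new
  neurons — the dissociation the generator exists to emulate. (Letting
  persisting neurons spawn couples "new" branching to persistence and
  destroys that dissociation.)

Each activation carries amplitude 1.0 by default, so count-based and
λ-based sizes coincide in tests; a neuron activated several times in a
frame is active once with amplitudes summed.

Defaults are the recording geometry above with `offspring_mean = 0.42`.
The two cohort presets differ only in persistence: `sal`
(`persist_prob = 0.05`) and `pcp` (`persist_prob = 0.25`), phenomenological
values fixed by direction (elevated burst persistence), not fitted to
any measured group mean. `drive_rate = 0.15` seeds/frame keeps the
per-neuron rate near 0.06 Hz while leaving most clusters single
cascades; at much higher drive, independent cascades concatenate into
long clusters, which inflates pooled branching ratios and makes burst
truncation fission clusters. The oracle tests push drive still lower
(0.004–0.05) because cluster merging biases the pooled branching ratio
upward by roughly 2 · drive · E[T] · E[S].

The `critical` preset (branching ratio 1, 500 neurons, low drive) is a
laptop-scale approximation of the critical regime. The theory-anchor
computations below use a larger ensemble.

What the generator does *not* emulate: slow cortical state fluctuations
(up/down states, anesthesia depth), refractoriness, distance-dependent
connectivity, and indicator nonlinearity. Consequently control-preset
spike trains are only marginally super-Poisson (median CV(ISI) ≈ 1.0;
the high-persistence preset reaches ≈ 1.25, and the pooled default
cohort median is ≈ 1.1), and passing tests say nothing about those
features of real recordings.

## Fluorescence forward model and deconvolution

The forward model is an AR(1) indicator kernel:
F(t) = γ·F(t−1) + λ(t) + ε(t), γ = exp(−1/(rate·τ_decay)), with white
noise entering the recursion, so the exact inverse
λ(t) = max(0, F(t) − γ·F(t−1)) recovers λ plus white noise.
`preprocess.deconvolve` subtracts the per-neuron median first (offset
invariance: a constant trace must deconvolve to silence), inverts, and
thresholds at `threshold_k` times a robust noise scale
(1.4826·MAD(diff F)/√2). The default `threshold_k = 5` reflects that
the threshold is applied independently at ~4·10⁵ neuron-frames per
movie: at 3 SD the expected false-event count is in the thousands,
at 5 SD it is near zero while unit-amplitude transients are never
missed. A tiny absolute floor (10⁻¹⁰ of the trace scale) absorbs
floating-point residue so noiseless round-trips recover the activity
mask exactly.

## Surrogates and pairwise metrics

`shuffle_raster` permutes each neuron's circular inter-event intervals
and re-lays them from a random start frame: event count and the
circular ISI multiset are preserved exactly, cross-neuron timing is
destroyed. Pair metrics (zero-lag Pearson r of the λ series; event
synchronization Q with an adaptive window of half the minimum
neighboring ISI, capped at 2 frames — longer windows at 15 Hz would
conflate separate transients) are corrected by subtracting the mean
over 20 shuffles (z-scoring available). Undefined pairs (zero variance
or no events) are excluded rather than zero-filled. Correlation
histograms default to width 0.01 on [−0.2, 0.6].

## Avalanche statistics

Clusters are maximal runs of consecutive frames with ≥ 1 active ROI.
Sizes are activation counts (or summed λ); durations are frame counts.

Size distributions are log-binned with geometric factor-2 bins from
s_min = 1, density = probability mass / bin width. For integer sizes
each bin is plotted at the geometric mean of its *integer support*;
plotting the singleton bin {1} at √(lo·hi) would set it ~70% above the
continuum line and bias the fitted slope by ≈ +0.1 (verified against
inverse-CDF samples from discrete power laws with τ ∈ {1.2, 1.5, 2.0},
where the least-squares fit recovers τ within 0.02).

The exponent is fitted by least squares on log center vs log density
over occupied bins lying **fully** inside [s_min, cutoff] (a bin
straddling the cutoff has its density diluted by the truncated part of
its width). The cutoff defaults to the system-size prediction: N for
count sizes, N × mean single-activation amplitude for λ sizes. A
discrete truncated maximum-likelihood estimator is provided as a
cross-check (`method="mle"`); the two agree to < 0.01 on clean samples.

The KS distance is the sup-distance between the empirical size CDF and
the fitted power-law CDF on [s_min, cutoff]. For integer sizes the
reference is the discrete (zeta-normalized) truncated power law and the
sup is taken at the atoms; comparing integer data against a continuous
CDF would report a spurious distance ≈ P(1). The distance against the
fixed mean-field exponent 3/2 is reported alongside; the best-fit
version is the default diagnostic.

The scaling exponent χ is a least-squares line on log T vs log ⟨s⟩(T)
over durations with ≥ 10 clusters; duration-1 clusters are included.

### Finite-size and finite-sample behavior of the theory anchors

Both anchors converge to their mean-field values from below.

- The fitted exponent of a near-critical ensemble sits at ≈ 1.43–1.45
  rather than 1.50: the single-cascade size law (Borel distribution)
  lies slightly below s^−3/2 at small s, cluster merging moves mass
  upward in size, and network collisions fold mass from beyond the
  cutoff into the upper bins.
- χ fitted over all durations approaches 2 very slowly: the small-T
  discrete-time corrections dominate until the pooled ensemble contains
  durations in the hundreds. At the ensemble scale used for the
  reproduction runs (40 movies × 10⁵ frames, 6000 units, ≈ 1.2·10⁵
  clusters, durations to ≈ 300) the fit yields χ ≈ 1.82; the same
  estimator on ≳ 10⁶ pure Galton–Watson trees reaches ≈ 1.92. The
  population size 6000 was chosen so that collision-induced tail
  suppression does not cap χ below the convergence trend (a 500-unit
  network saturates near 1.6 regardless of sample size).

These problem sizes are the package's reproduction conditions and are
fixed in `scripts/acceptance.py` and the acceptance tests.

## Branching parameters, bursts, intervention

Temporal σ: total λ in frames after the first of a cluster divided by
first-frame λ. Spatial σ: the same with activation counts, with each
downstream activation labeled *repeat* if that ROI was active earlier
in the same cluster, else *new*; new + repeat = total exactly, in both
estimator modes. The pooled ratio (sum over clusters of numerators /
denominators) is the default; the per-cluster mean is computed
alongside because neither convention is canonical. First-frame
activations are ancestor context only (neither new nor repeat). A
repeat need not be consecutive; consecutive-frame runs are measured
separately as bursts.

Bursts are per-neuron maximal runs of consecutive active frames. The
burst-length slope β is a log-log least-squares line over occupied
lengths (undefined below 3 occupied lengths); the multi-frame fraction
is #(L > 1)/#bursts.

`remove_persistent_bursts` selects round(fraction × count) multi-frame
bursts (nearest integer, ties up — a deterministic rule was needed)
uniformly without replacement and zeros all activity after each
selected burst's first frame. It never creates activity and never
moves first frames.

## Statistics

Group comparisons are gated on normality: Shapiro–Wilk per group at
α = 0.05; all groups normal → Welch t / paired t / one-way ANOVA with
Tukey HSD; otherwise Wilcoxon rank-sum / signed-rank / Kruskal–Wallis.
All tests two-tailed at α = 0.05. A constant sample is routed to the
rank-based branch (Shapiro–Wilk is undefined there). Per-bin histogram
comparisons use uncorrected rank tests per bin (the output records that
no multiplicity correction was applied) plus the sup-distance between
group-averaged CDFs, and a two-sample KS test when pooled raw values
are supplied — averaged-CDF and pooled variants are both emitted
because neither is canonical. The movie is the unit of analysis; animal
identity can be carried in provenance but no hierarchical model is fit.

Type-I calibration of the gated two-group test is part of the test
suite: 2000 null simulations per gate branch stay within [0.03, 0.07]
at α = 0.05.

## Numerical and engineering choices

- Simulation runtime scales with active frames, not recording length
  (silent stretches are skipped by sampling the geometric gap to the
  next seeding frame); per-frame accumulation touches only hit neurons.
- Very large simulations use float32 rates (`dtype=` argument); all
  default-scale analyses use float64.
- `SpikeRaster` validates its invariants on construction; internal
  producers that build rates themselves may skip the full-array scans
  (`check=False`).
- Determinism: every stochastic routine takes a seed; cohorts and
  shuffle ensembles derive independent child streams from one root
  seed via `SeedSequence` spawning.

## Known limitations

- The branching readouts of the cohort presets sit above the
  single-cascade value m/(1−m) because sustained drive still merges
  some cascades; the textbook interpretation (σ < 1 subcritical)
  applies cleanly only in the low-drive regime.
- The power-law and scaling fits are least-squares on binned data by
  design (matching the conventional presentation of avalanche
  distributions); the MLE cross-check covers the exponent only.
- Event synchronization is O(pairs × events²) and intended for fields
  of ~100 neurons, not thousands.
- No shape-collapse analysis, no subsampling correction, no time-bin
  optimization: the imaging frame is the bin.
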