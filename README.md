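# avakit

Neuronal-avalanche and branching-process analysis of two-photon
calcium-imaging population activity.

## The problem

In vivo two-photon imaging yields ΔF/F traces for ~10²–10³ neurons of a
local cortical population at video rate. A recurring question in
systems and computational neuroscience is whether, and how, the
spatiotemporal propagation of spontaneous activity deviates from the
near-critical regime observed in healthy cortex — for example in
disease models where single-neuron burst persistence distorts cascade
propagation. `avakit` provides the full analysis chain for that
question, plus a controlled synthetic-data generator so every stage can
be validated against branching-process theory.

## What it computes

Starting from ΔF/F traces (or a precomputed spike-rate raster λ):

- **Deconvolution** — AR(1) inversion with robust SD thresholding:
  λ(t) = max(0, F(t) − γ·F(t−1)), γ = exp(−1/(rate·τ_decay)).
- **Pairwise synchrony** — zero-lag correlation r and event
  synchronization Q (adaptive coincidence window), both corrected by
  subtracting the mean over ISI-preserving circular-shuffle surrogates.
- **Neuronal avalanches** — spatiotemporal clusters of consecutive
  active frames; log-binned size distributions; power-law exponent τ
  fitted by least squares up to the system-size cutoff
  (P(s) ∝ s^−τ, τ = 3/2 at mean-field criticality); KS distance to the
  fitted power law; size–duration scaling ⟨s⟩(T) ∝ T^χ (χ = 2 at
  criticality).
- **Branching parameters** — temporal σ (descendant λ over first-frame
  λ per cluster; σ = 1 marks criticality) and spatial σ in neuron
  counts, decomposed exactly into *new* and *repeat* activators.
- **Bursts and intervention** — per-neuron runs of consecutive active
  frames, burst-length slope β and multi-frame fraction, and the causal
  intervention that truncates a random fraction of multi-frame bursts
  after their first frame.
- **Group statistics** — Shapiro–Wilk-gated comparisons (Welch t /
  rank-sum; ANOVA + Tukey / Kruskal–Wallis), per-bin distribution tests,
  JSON/CSV reports.

The generator (`avakit.synth`) simulates a driven branching process
with controllable branching ratio, spontaneous drive, and single-neuron
burst persistence, plus a fluorescence forward model and ROI geometry —
presets emulate a control-like cohort, a burst-persistent cohort, and a
near-critical network. See `docs/methods.md` for the model and all
estimator conventions.

## Worked example

```bash
avakit simulate --preset sal --seed 7 --out sal.h5
avakit analyze avalanches sal.h5 --outdir out/
avakit analyze branching sal.h5
avakit analyze bursts sal.h5
```

prints (abridged):

```
{
 "n_clusters": 556,
 "exponent": 2.407705358838849,
 "ks_distance": 0.24705821522548688,
 "scaling_exponent": 1.1536327690461927
}
{
 "sigma_temporal": 1.2585924713584289,
 "sigma_spatial_new": 1.09328968903437,
 "sigma_spatial_repeat": 0.16202945990180032
}
{
 "n_bursts": 1291,
 "slope": 5.100227520946153,
 "fraction_multiframe": 0.061192873741285826
}
```

Read: this 80-neuron, 5000-frame control-like movie decomposes into 556
avalanches whose size distribution falls off steeply (fitted exponent
2.4 — a subcritical cascade with branching ratio 0.42 at this movie
size, far from the heavy-tailed critical value 1.5), with repeat
activation contributing only 0.16 of the spatial branching and 6% of
single-neuron bursts lasting more than one frame. The same commands on
`--preset pcp` (elevated burst persistence) yield a shallower size
distribution, repeat branching near 0.5, and a multi-frame burst
fraction near 0.26; `avakit intervene remove-bursts --fraction 0.3333`
moves those numbers back toward the control values.

The same pipeline is available as a library:

```python
from avakit import (PRESETS, simulate_branching_raster, extract_clusters,
                    size_distribution, fit_power_law)
raster = simulate_branching_raster(PRESETS["critical"])
clusters = extract_clusters(raster)
fit = fit_power_law(size_distribution(clusters), cutoff=raster.n_neurons)
print(fit.exponent, fit.ks_distance)
```

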