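# Methods

This note documents the models, conventions and numerical choices behind
`spikecompat`, and what its synthetic testbed does and does not establish
about real recordings.

## Recording model and preprocessing

A recording is a single-channel voltage trace with optional ground truth:
strictly increasing spike times (0-based sample indices) and integer class
labels 1..L. Spike *detection* is deliberately out of scope — the whole
point of the testbed is to isolate the clustering stage, so ground-truth
times are consumed directly.

Band-pass filtering removes field potential before waveform extraction:
4th-order Butterworth, 300–3000 Hz, applied forward–backward
(`sosfiltfilt`) so it is zero-phase and spike peaks are not displaced.
These band edges are the conventions of the single-unit literature; both
edges and order are config keys. Simulated traces contain no field
potential, so the runner skips filtering by default (`apply_filter: true`
restores it).

Waveform extraction cuts a 64-sample window per event: 20 samples left of
the peak, 44 right, the peak occupying the 20th sample (1-based). A
provisional window is cut at the event time, the peak located, and the
window re-cut at the peak; the re-cut iterates (default 8 times) because a
larger sample can enter at a window edge. "Peak" means the most positive
sample by default — the benchmark templates are positive-peaked — with an
`absmax` mode for negative-going data (such pools skip the positive-peak
alignment check). Events whose final window would cross the trace bounds
are dropped, never padded (padding would distort features); the drop count
is logged for audit.

## Synthetic data generator

The generator emulates the three benchmark regimes: *low* spike-shape
similarity (easy), *high* similarity (difficult), and a pre-extracted
waveform-pool mode standing in for curated real data.

Templates are 64-sample, unit-peak shapes built from generalized-Gaussian
primitives (exp(−|t/s|^p/2): p=1 a sharp cusp, p=2 Gaussian, p=3
flat-topped), combined into four families — sharp cusp with a late
after-hyperpolarization, broad flat-topped wave, triphasic spike with deep
pre- and post-lobes, and a double-humped slow wave — each with seeded
jitter in width, lobe depth and delay. The similarity *regime* is the
contract, measured as normalized cross-correlation at lag 0 between
aligned templates: low similarity requires every pairwise correlation
below 0.7 (distinct families per class), high similarity every pairwise
correlation above 0.9 (jittered copies of one base shape). Draws violating
the constraint are rejected and redrawn (bounded retries, deterministic
per seed); the thresholds are arguments.

A simulated recording is the sum of templates placed at spike times plus
white Gaussian noise. Key parameters:

| parameter        | default | units                         | why |
|------------------|---------|-------------------------------|-----|
| `n_classes`      | 3       | —                             | the synthetic benchmarks use 3 classes (real data 4; supervised n follows suit) |
| `n_spikes`       | 600     | spikes                        | large enough for stable indices, small enough for second-scale runs |
| `noise_sd`       | 0.05    | template peak amplitudes      | emulates the benchmarks' lowest noise level (~0.05–0.1 of peak) |
| `min_separation` | 100     | samples                       | ≥ one 64-sample window, so extracted spikes never overlap |
| `sampling_rate`  | 24000   | Hz                            | convention of the source datasets when unstated |

Class labels are near-uniform: counts differ by at most one, and are
exactly balanced when `n_spikes` is a multiple of `n_classes`; order is
shuffled per seed. An `overlap_fraction` knob exists (spikes closer than a
window) but defaults to 0, since the evaluation treats spikes as extracted
windows.

`simulate_waveform_pool` skips trace assembly: each row is its class
template plus strictly i.i.d. Gaussian noise, so per-class row means
converge to the templates at rate noise/√n (a property the tests verify).
The empirical maximum of a noisy row may sit a sample or two off the
template peak; the pool is *not* re-aligned on it, because conditioning on
the noisy argmax biases the mean near the peak (measurably, ~0.1 peak
units for flat-topped templates at noise 0.1). The strict empirical-peak
invariant is instead guaranteed by the trace-extraction path.

What the generator does **not** model: bursting, electrode drift,
amplitude attenuation, correlated or non-Gaussian noise, overlapping
spikes (by default), and multi-channel geometry. Passing tests on this
testbed therefore show that an algorithm separates template-shaped
clusters under white noise at a given shape similarity — not that it
survives drift or overlap on a real probe.

## Feature-sets

**PCA (d=3).** Waveforms are mean-centered and projected onto the three
largest-variance components. Three components is the binding rule; the
fraction of variance they cover is reported in metadata (on the benchmark
datasets it is around 95%) but never enforced, because arbitrary pools
cannot guarantee both. A pool whose centered rank is below 3 is an error
naming the achieved rank — notably, a zero-noise 3-class pool has centered
rank 2, so the wavelet route is the well-defined one there.

**Wavelets (d=10).** Each waveform is decomposed with a 5-level orthonormal
Haar DWT (PyWavelets, periodization mode; exact energy conservation on the
dyadic 64-sample window). For each of the 64 coefficient positions, the
deviation of its empirical distribution across the pool from normality is
measured with a Lilliefors-style Kolmogorov–Smirnov statistic (standardize
by sample mean and ddof-1 sd, sup distance between the empirical CDF and
Φ). No p-values: only the *ranking* matters, and multimodal coefficients —
the ones carrying class structure — rank high. The 10 highest-deviation
coefficients are selected (ties to the lower index, for determinism) and
their raw values form the feature matrix; selected indices are recorded in
metadata. Coefficients constant across the pool carry no information and
score 0 (the variance guard uses a 1e-12 relative tolerance to absorb
last-bit rounding of "identical" values); an all-degenerate pool falls
back to the first 10 coefficients with a warning.

**KNN graph.** For graph-based clusterers, a directed K=11 nearest-neighbor
graph with Euclidean weights is exported as 1-based `source target weight`
text lines. Consumers needing symmetry symmetrize explicitly.

## Clustering harness

Supervised algorithms receive the partition count n (3 for synthetic, 4
for real data, per dataset in the config); unsupervised ones determine
their own structure and may return one cluster, many, or nothing — all
three regimes are scored. Euclidean distance throughout. Labels are
densely re-indexed 1..k on construction. n=1 is answered directly with the
single trivial partition.

Adapters wrap scikit-learn (k-means, agglomerative, BIRCH, spectral,
Gaussian mixture, variational Gaussian mixture, affinity propagation,
mean-shift, DBSCAN, OPTICS). K-medoids (Voronoi-iteration PAM style) and
fuzzy c-means (m=2, memberships hardened by arg-max) are implemented here,
as no maintained implementation exists in the dependency set. All
stochastic adapters take explicit seeds; k-means-family adapters use 10
restarts with the best inertia kept. Further algorithms register via
`register_adapter`.

Failure semantics: an adapter exception degrades to an *empty* partition
with a logged diagnostic — a grid evaluation never aborts on one
algorithm. DBSCAN/OPTICS noise points are pooled into one extra cluster
(accuracy keeps its total-M denominator and every spike stays auditable);
if everything is noise the partition is empty.

## Scoring

**Confusion matching.** Classes and clusters are matched one-to-one,
greedily by descending co-occurrence count. Tie order: lower class label,
then the cluster's full per-class count column, then the cluster label.
The column signature makes the matching invariant under any relabeling of
clusters — a property the scores must have and that a plain
lower-cluster-label tie-break violates (two clusters tied for one class
can swap with their labels) — while clusters with identical columns are
genuinely interchangeable. Spikes in unmatched clusters are counted in
`discarded`, so matrix total + discarded = M always. An exhaustive
optimal-assignment mode (`matching: optimal`, Hungarian) exists; tests
verify greedy never exceeds it and quantify the gap. Greedy is the default
for transparency and auditability.

**External indices** are computed from the contingency table with exact
binomial-coefficient pair counts; tests check them against an O(M²)
enumeration to 1e-12. Empty partitions score Rand 0 and Jaccard 0 with a
"no index produced" flag, matching the convention that a failed algorithm
is worst-case.

**Internal indices.** BH = mean over clusters of mean squared distance to
the barycentre; TrW = total within-cluster squared distance (unnormalized,
grows with M by design); DB = the usual mean worst-pair ratio of
dispersions to centroid distance. DB requires k ≥ 2 and distinct
centroids; undefined cells are flagged (NaN), never imputed. BH and TrW
are defined for a single cluster (global scatter).

**NII normalization** Î = 1 − |r − i| / (max(I) − min(I)) includes the
reference r (the ground-truth index) in the range set, so Î is guaranteed
to be in [0, 1] even when ground truth lies outside the observed range,
and Î(ground truth) = 1 exactly. A degenerate range (all values equal)
maps to 1 where i = r, else 0.

**Consistency and categories.** The inverted RMSE uses the square root (as
the name demands) and, by default, Rand only — Jaccard can fail to produce
values for degenerate results; a config flag adds it, which can swap
rankings below the middle categories. Categories come from rank quintiles
over the non-ground-truth algorithms by default (no published thresholds
exist for the six bins); fixed thresholds are a config option. The NII
variance (population variance of the DB/BH/TrW triple) is reported per
algorithm × feature-set as the index-consistency diagnostic: high variance
marks an incompatible algorithm even when a single index looks good.

**Partition-selection rules** for sweeping candidate counts: DB uses the
minimum score, BH and TrW the maximum second difference; minimum/maximum
second difference and maximum-difference-to-left are also available. Ties
resolve to the smaller partition count.

## Determinism and problem sizes

Every stochastic step (template draws, labels, noise, clustering restarts)
is driven by explicit integer seeds; identical config + seeds reproduce
score tables byte-for-byte, and outputs carry a config snapshot but no
timestamps. The shipped example and the test suite use pools of 240–3,000
spikes — large enough that accuracies and indices stabilize (the
single-cluster degenerate case gives Rand 0.33 and accuracy 33.3% on 3×1,000
balanced spikes), small enough that a full grid runs in seconds on one
core. Statistical checks (class-mean convergence, noise-vs-accuracy trend,
parameter recovery over 10 seeds) use fixed seeds and bounds with explicit
multiple-comparison corrections where a maximum over many samples is
taken.

## Known limitations

- The registry wraps a representative subset of the clustering literature;
  spike-sorting-specific sorters (superparamagnetic clustering,
  Klustakwik, ISO-SPLIT, Chameleon, CURE, ROCK, CAST, DIANA, and the
  protein-interaction graph clusterers) have no maintained implementations
  in the dependency set and are extension points, not results.
- Internal indices on single-cluster partitions ignore DB (undefined);
  rankings built from two indices instead of three are flagged in the NII
  variance column.
- Quintile category bins are a convention, not a published calibration;
  with few algorithms the bins are coarse.
- The reader recognizes the common public container dialects (trace +
  `spike_times`/`spike_class`, one level of cell nesting; pre-extracted
  `spikes` + `cluster_class`); exotic layouts need the configurable name
  lists.
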