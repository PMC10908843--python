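# Methods

## Signal model and preprocessing

A session recording is a 40 Hz conductance series in microsiemens with event
markers delimiting, per imagery scene, a 5 s pre-script baseline, a guided
script window (default 45 s; script lengths vary in practice, so this is
configurable) and a 60 s self-produced imagery window. Scenes are contiguous;
six analysis scenes are used for inference and an optional squat "test"
scene is segmented and normalized but excluded from the primary analyses
(it exists for the design's power check).

Cleaning applies the Tukey fence at 1.5·IQR per person per scene×phase
segment, one pass, with quartiles by linear interpolation between order
statistics (`numpy.percentile` default). Cleaning is per segment rather than
per recording because the tonic level drifts across a session: a
whole-session fence removes valid early/late samples. The scope is exposed
as a config switch (`clean_scope`), with `segment` the default. Removed
samples are dropped, not interpolated; surviving time stamps are kept, which
the slope regression and (after block resampling) DTW tolerate.

Normalization divides each script window by the mean of the *cleaned* 5 s
window ending at script onset: nSCL_t = 100·(x_t − b)/b. Both script
windows of a scene share that scene's pre-script baseline, so the
self-produced window inherits the drift accumulated during the guided
window. This is a property of the design worth noting: even with identical
drift parameters in both windows, the self-produced mean nSCL sits lower.
The modality comparison of *slopes* is free of this artifact, which is why
the type-I-error study uses the slope feature.

## Features

* `nSCL_mean`, `nSCL_var` (sample, n−1 denominator), and `nSCL_slope` (OLS
  coefficient of nSCL on time in seconds) are computed on the normalized
  series.
* `nSCL_nfsc` counts fluctuations (nonspecific skin conductance responses)
  per minute. Counting operates on the cleaned raw μS series because the
  amplitude criterion is stated in μS and would be baseline-dependent on the
  percent scale (a normalized-scale mode exists behind `nfsc_on_raw=False`,
  which rescales both thresholds by 100/b). The detector smooths with a
  0.5 s moving average (40 Hz quantization and sensor noise otherwise
  produce spurious micro-peaks), finds local maxima, locates the preceding
  trough, and counts peaks with trough-to-peak rise ≥ 0.02 μS whose mean
  rise slope is < 2 μS/s. The slope cutoff is an artifact rejection: a step
  discontinuity smoothed over 0.5 s rises at ≥ 2 μS/s and is excluded.
  Counts are normalized by window duration to events/min, so guided windows
  of any length are comparable with the 60 s self-produced windows.

## Statistical tests

Guided-vs-self contrasts are paired over (person, scene) — 180 pairs for a
30-person, six-scene cohort — and use the Wilcoxon signed-rank test with
zero differences discarded and midranks for ties. The reported statistic is
W = min(W⁺, W⁻); p-values are exact for n ≤ 25 without ties and otherwise
come from the tie-corrected normal approximation (via `scipy.stats`).
Tier contrasts (Tiers 1–3 vs. Tier 4, independent samples) use the
Mann–Whitney U test with U reported for the Tiers 1–3 group,
U = R₁ − n₁(n₁+1)/2; exact p for n₁·n₂ ≤ 400 without ties. Feature-level
outliers are removed per feature and group with the same 1.5·IQR fence
before testing. No multiple-testing correction is applied (none is part of
the analysis being reproduced).

Direct sign-pattern counts classify each participant by the scene-wise
majority direction of the self−guided difference; a participant whose
absolute mean difference is below 5% of the pooled feature SD counts as
"almost the same" (the tolerance is configurable, as the notion is
inherently fuzzy). The standardized mean difference is d = |Δ|/σ, and
`t_power` evaluates two-sided power from the noncentral t distribution
(noncentrality d·√n for one-sample/paired designs, d·√(n/2) with 2n−2 df
for two-sample). Which design and n underlie a published power figure is
often unrecoverable; the function is generic rather than tied to one case.

## Shape similarity (DTW)

Series are reduced to 4 Hz by non-overlapping block means (tonic SCL
bandwidth is well below 1 Hz; a 60 s window becomes 240 samples, shrinking
the DTW table 100-fold) and z-normalized, so comparisons see shape only —
similarity is invariant to per-person amplitude and offset. The DTW
distance is the classic dynamic program with absolute local cost,
D(i,j) = |a_i − b_j| + min(D(i−1,j), D(i,j−1), D(i−1,j−1)), unconstrained
by default (a Sakoe–Chiba band width is exposed). Distances within one
scene×modality condition map to a 0–100 similarity by per-condition
min–max scaling S = 100·(1 − d/d_max); the transform is isolated in one
function because the 0–100 scale is intrinsically arbitrary (only order
and the endpoints are meaningful — within-tier similarity *values* are
therefore comparable only within one analysis, not across datasets).
Per-scene matrices are averaged element-wise per modality; participants
excluded from some conditions (degenerate constant segments) are averaged
over the conditions where both pair members are present, with counts
reported. Within-tier similarity is the mean off-diagonal entry among
members of a tier; singleton groups are reported as missing.

## k-Shape clustering and consensus

k-Shape operates on z-normalized, equal-length series (each condition's
series are truncated to its shortest length; with the default generator all
lengths in a condition are equal). The shape-based distance is
SBD(x, y) = 1 − max_w NCC_w(x, y) over all integer shifts with zero
padding, computed via FFT cross-correlation; it lies in [0, 2] and is
shift-invariant. Note that SBD(x, −x) < 2 in general: the shift search
finds whatever positive correlation exists at some lag, so 2 is attained
only when correlation is −1 at *every* lag. Centroids are the leading
eigenvector of the centered scatter of members aligned to the current
centroid, sign-chosen to correlate positively with the members, then
z-normalized. Initialization is a seeded random partition; 10 restarts keep
the partition with the lowest total member-to-centroid SBD; empty clusters
are reseeded from the worst-fit series. The per-iteration objective is
non-increasing, and runs are deterministic given the seed. A partition is
flagged degenerate when fewer than k clusters are populated or the
objective is ~0 with more series than clusters (all series alike — the
reseeding rule then holds clusters apart artificially).

Partitions are validated with the silhouette score on the SBD distance
matrix (same geometry the clusterer optimizes; DTW distances can be
substituted), with the standard singleton-cluster convention s(i) = 0.
Consensus counts, for each pair, the number of conditions assigning both to
the same cluster (0–12; invariant to per-condition label flips) and keeps
pairs with count ≥ 10 (configurable) as edges of a connectivity graph with
tier-annotated nodes.

## Synthetic session generator

The generator emulates the statistical structure the analysis assumes,
not sudomotor physiology:

* **Tonic level**: per person uniform on 2–15 μS; per-segment linear drift
  drawn from a normal distribution per (modality, tier). Drift is specified
  in percent of the person's tonic base per second — the effects being
  emulated live on the normalized scale, and absolute μS/s drifts would make
  percent-scale features scale as 1/baseline, letting low-baseline
  participants dominate. Defaults (%/s, mean ± sd): guided −0.024 ± 0.112
  (Tiers 1–3) and −0.068 ± 0.046 (Tier 4); self-produced −0.044 ± 0.091 and
  −0.054 ± 0.053. Tier 4 drifts are steeper (faster habituation) but less
  dispersed (more mutually similar shapes). The self-produced dispersions
  are set above what the slope statistics alone would suggest so that
  within-window nSCL variance is higher in self-produced imagery, matching
  the modality variance ordering; within-window variance of a drifting
  segment grows as E[s²]·T²/12, so dispersion, not mean, controls it.
  Positive drift draws are capped at +0.1%/s: sustained steep tonic rises
  are not physiological and, uncapped, masquerade as countable fluctuations.
* **Phasic events**: Poisson event times per segment at per-(modality, tier)
  rates (events/min): guided 1.5 / 0.9, self-produced 3.3 / 2.3
  (Tiers 1–3 / Tier 4), baseline 1.2 / 0.8. Each event adds a
  peak-normalized biexponential (Bateman) kernel
  k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r), τ_r = 0.7 s, τ_d = 3.0 s, with lognormal
  amplitude (median 0.12 μS, σ_log 0.5), comfortably above the 0.02 μS
  counting threshold. Kernels spill across segment boundaries, as real
  responses do.
* **Noise and floor**: white Gaussian noise (sd 0.008 μS) and a 0.05 μS
  conductance floor.

Defaults target the *orderings* of the modality and tier effects (lower
mean, higher variance, more fluctuations in self-produced; lower variance,
fewer fluctuations, steeper slope and more similar shapes in Tier 4), not
any particular dataset's printed values — those depend on the cohort. A
`null_modality_config` helper equalizes drift and rate across modalities
for type-I-error studies. All randomness flows from one seeded
`numpy.random.Generator`; output is bit-reproducible per seed.

What the generator does **not** emulate — and hence what passing tests do
not establish about laboratory data: motion and pressure artifacts beyond
an occasional IQR-detectable outlier, electrode drift and contact loss,
respiration coupling, non-Poisson (stimulus-locked) response clustering,
inter-scene carry-over beyond kernel spillover, or any EEG/cardiac channel.

## Recovery studies and problem sizes

`sclshape.experiments` packages the seeded validation studies used by the
test suite and `scripts/acceptance.py`:

* `modality_recovery_study`: 100 replicates of the default 30-person,
  six-scene cohort at 40 Hz; rejection rates of the paired Wilcoxon tests,
  optionally under the modality-null configuration (where only the slope
  comparison is a clean null; see the baseline-inheritance note above).
* `tier_similarity_study`, `consensus_enrichment_study`: one cohort each;
  within-tier DTW similarity per modality, and the fraction of 10-of-12
  consensus edges joining two Tier-4 nodes against the random-pairing
  expectation C(9,2)/C(30,2) ≈ 0.083.
* `shape_recovery_study`: 2×15 series of length 240 from two fixed smooth
  templates at noise sd 0.05; adjusted Rand index of k-Shape at k = 2 and
  the silhouette ordering across k = 2, 3, 4.

The fluctuation detector recovers configured SCR rates to within about
−10%: closely spaced events (≲1.5 s) merge into one smoothed peak, and
steep negative drift masks the smallest amplitudes. This bias is inherent
to trough-to-peak counting without deconvolution and is shared by the
modalities, so paired contrasts are unaffected.

## Numerical choices and degenerate inputs

* Quartiles: linear interpolation; one-pass fence (no re-computation after
  removal); a fence that removes everything raises rather than returning an
  empty segment.
* Constant series: flagged degenerate by `znorm` and excluded from
  similarity; constant segments have variance 0 and slope 0 by definition.
* DTW of empty series, baselines ≤ 0, overlapping event markers, duplicate
  feature keys, k outside [2, n], and silhouette with one cluster all raise
  typed errors (`sclshape.errors`).
* The DTW inner loop is numba-compiled; the SBD cross-correlation uses FFT
  lengths padded to `scipy.fft.next_fast_len`.

## Limitations

The pipeline reproduces an analysis protocol; on real data the absolute
0–100 similarity values and silhouette scores depend on choices the
protocol leaves open (distance-to-similarity transform, series-length
harmonization, k-Shape initialization), so only their orderings and
threshold-crossings should be interpreted. The feature set deliberately
stops short of SCR decomposition (amplitudes, latencies, deconvolution),
and no attempt is made to parse proprietary biofeedback-device exports.
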