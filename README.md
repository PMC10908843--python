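# sclshape

Analysis pipeline for skin-conductance-level (SCL) recordings collected while
athletes perform **guided** (listening to a pre-recorded script) versus
**self-produced** (unassisted) mental imagery. SCL — the slow tonic component
of electrodermal activity, in microsiemens (μS) — indexes sympathetic arousal;
the package asks two questions of a multi-scene imagery session:

1. Does the instructional modality change the electrodermal response
   (level, variability, habituation slope, number of phasic fluctuations)?
2. Does the *shape* of the response separate athletes by expertise tier
   (Tiers 1–3, recreational to national level, vs. Tier 4, international)?

It is written for psychophysiology researchers who have per-participant SCL
traces (40 Hz, μS) with event markers delimiting, per imagery scene, a 5 s
pre-script baseline, a guided script window and a 60 s self-produced window.
A seeded synthetic electrodermal-activity session generator with ground truth
is included, so the entire pipeline is testable without laboratory data.

## Method

**Preprocessing.** Each scene×phase segment is cleaned by the 1.5·IQR rule
(points outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] removed, quartiles by linear
interpolation) and expressed as percent change from the pre-script baseline:

    nSCL_t = 100 · (x_t − b) / b,   b = mean SCL in the 5 s before script onset.

**Features.** Per (person, scene, modality): `nSCL_mean`, sample variance
`nSCL_var`, ordinary-least-squares slope `nSCL_slope` (%/s), and `nSCL_nfsc`
— fluctuations per minute, counted on the raw μS series as smoothed local
maxima with trough-to-peak rise ≥ 0.02 μS and mean rise slope < 2 μS/s.

**Inference.** Guided vs. self-produced contrasts are paired per
(person, scene) and tested with the Wilcoxon signed-rank test
(W = min(W⁺, W⁻)); tier contrasts use the Mann–Whitney U test
(U reported for Tiers 1–3). Feature-level outliers are removed by the same
1.5·IQR rule before testing. A standardized mean difference d = |Δ|/σ and
noncentral-t power computation support the design check against the unused
test scene.

**Shape analysis.** Series are block-averaged to 4 Hz and z-normalized, so
only shape remains. Dynamic time warping (absolute local cost, classic
recurrence) gives pairwise distances, mapped per condition onto a 0–100
similarity scale via S = 100·(1 − d/d_max) and averaged over scenes.
k-Shape clustering (shape-based distance SBD = 1 − max-shift normalized
cross-correlation; eigenvector centroids) partitions each of the 12
conditions (6 scenes × 2 modalities) into k = 2 clusters, validated by the
silhouette score; a consensus count of pairwise co-assignments (0–12),
thresholded at 10, yields a connectivity graph whose edges concentrate
within the expertise tier that shares a response shape.

## Worked example

```python
from sclshape import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_scenes=6, outdir="demo_out")
res = run_pipeline(cfg)   # simulates a 30-person cohort, runs every stage

print(res.features.groupby("phase")[
    ["nSCL_mean", "nSCL_var", "nSCL_slope", "nSCL_nfsc"]].mean().round(2))
for rep in res.wilcoxon:
    print(f"{rep.feature:11s} W={rep.statistic:7.1f}  p={rep.p:.2e}  {rep.direction}")
print(res.tier_similarity)
```

prints

```
        nSCL_mean  nSCL_var  nSCL_slope  nSCL_nfsc
phase
guided      -0.91      2.43       -0.04       1.19
self        -3.41      3.51       -0.05       2.52
nSCL_mean   W= 2228.0  p=2.68e-15  guided>self
nSCL_var    W= 3747.0  p=1.09e-05  guided<self
nSCL_slope  W= 6678.0  p=7.92e-02  guided>self
nSCL_nfsc   W= 1400.5  p=2.02e-18  guided<self
{'guided': {'tiers1_3': 52.5, 'tier4': 83.3}, 'self': {'tiers1_3': 59.7, 'tier4': 62.4}}
```

Self-produced imagery shows a lower mean nSCL, higher variance and more
fluctuations than guided imagery (all significant), no modality difference
in slope, and Tier-4 athletes' signal shapes are mutually more similar than
those of Tiers 1–3 in both modalities. `demo_out/` receives the feature
table, test tables, similarity matrices, cluster assignments, consensus
graph and a run log, each stamped with the configuration hash.

The same stages are available from the shell:

```bash
sclshape simulate --out recordings.csv
sclshape preprocess --input recordings.csv --out segments.csv
sclshape features --input segments.csv --out features.tsv
sclshape stats --input features.tsv --outdir out/
sclshape similarity --input segments.csv --outdir out/
sclshape cluster --input segments.csv --out clusters.tsv
sclshape consensus --input clusters.tsv --outdir out/
# or everything at once:
sclshape run-all --seed 1 --outdir out/
```

## Data formats

Recordings travel as long-format CSV (`person_id,tier,scene,phase,t,scl_uS`);
normalized segments as tidy CSV; features, test tables, similarity matrices
and graphs as TSV. See `docs/methods.md` for modelling details, parameter
defaults and limitations.
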