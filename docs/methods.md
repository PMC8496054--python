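# Methods

This note documents the models and procedures implemented in `ccapipe`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and known limitations.

## IHC scoring and cross-tabulation

Cores are coded ordinally: quantity 0 (no positive cells), 1 (<1%), 2
(1–9%), 3 (10–50%), 4 (>50%); intensity 0–3 (none/low/medium/strong).
The core score is the product (range 0–12, only
{0,1,2,3,4,6,8,9,12} achievable) and the tumor score the mean of the
two cores; a tumor with a single evaluable core keeps that score and is
flagged rather than dropped, so it stays analyzable.  Class bins are
low ≤ 3, intermediate 3.5–7.5, high ≥ 8; every achievable two-core mean
falls into exactly one bin (verified by exhaustive enumeration), and
off-grid inputs are rejected rather than rounded.

Positivity defaults to *any staining* (mean score > 0).  This choice is
deliberate: it is the only rule consistent with cross-tabulations whose
counts exceed the intermediate+high classes, and it is exposed as a
configuration (`threshold`, `mode ∈ {greater, at_least}`) because the
criterion is a reporting convention, not a biological constant.  The
cross-tabulation's "exactly one marker" column is the symmetric
difference YAP + TAZ − 2·both; the third row is the per-marker union
over compartments.  Percentages are 100·count/n rounded to one decimal
(Python's round-half-even; at cohort sizes of 100–160 the choice of
rounding rule affects no reported value).  G3 and G4 tumors are merged
for grade associations because G4 strata are tiny (0–3 tumors).

## n/c ratio quantification

Segmentation is deliberately simple and deterministic: Gaussian
smoothing, Otsu threshold, connected components, minimum-area filter
(default 30 px) — the scientific content of the stage is the
subtraction/ratio logic, not the segmenter, and a deterministic
segmenter makes the stage reproducible and testable.  Defaults: sigma
2 px for the DAPI channel; sigma 0.5 px for the stain channel, because
the cytoplasmic rim is only a few pixels wide and heavier smoothing
erodes its outer edge before thresholding (with sigma 2 the recovered
cytoplasm covered only ~82% of the ground truth; with 0.5, ~98%).

The ratio is computed per field from field-level mean intensities (not
per cell).  The density threshold is the arithmetic mean nucleus count
over all fields with a defined ratio; counts strictly below it are
"low", ties and everything above are "high".  Fields with an empty
compartment are flagged `defined=False`, excluded from the threshold and
tests, and reported in `n_excluded` — never silently dropped.  Low vs
high density is compared by Mann-Whitney; the trend is summarized by OLS
of ratio on count.

Measured ratios carry a small negative bias (~3% at the default
geometry): segmentation masks include partial-volume edge pixels that
mix compartment and background intensities.  The bias shrinks with
larger cells and vanishes on ground-truth masks.

## CIN25 signature, clustering and survival

Counts are CPM-normalized (each sample scaled to 10^6), log2(CPM+1)
transformed, and each gene z-scaled across samples (mean 0, SD with
n−1 denominator).  Log transformation before scaling is the default
because scaling raw CPM lets single high-expression samples dominate a
gene's variance; it is toggleable.  The signature score is the sum of
scaled values over the signature genes, so each gene contributes
equally and scores sum to zero over the scaling population.  The
scaling population defaults to all samples in the matrix (tumors and
normals together, as a clustered heatmap displays them); zero-variance
genes contribute zero with a warning.

k-means (k = 3, Lloyd's algorithm, best of 25 seeded restarts by
within-cluster sum of squares) runs on the scaled signature submatrix —
i.e. on what the heatmap shows — rather than on the 1-D score;
clustering on the score is available by splitting the score vector
directly.  The median split assigns scores > median to "high" and ties
to "low" (a deterministic, documented direction).  A median split
necessarily dilutes a subgroup effect whose prevalence is far from 50%;
the cluster-based split (top-score cluster vs rest) is the sharper
stratification when a minority subgroup is planted, and both are
reported by the survival driver.

Kaplan-Meier estimation and the log-rank (Mantel-Cox) test delegate to
`lifelines`; the package's own tests pin them to a hand-computed
product-limit table and a permutation oracle.  The default CIN25 gene
list (`ccapipe/data/cin25_default.txt`) ships seven canonical CIN genes
(AURKA, AURKB, CCNB1, CCNB2, FOXM1, TOP2A, TTK) plus placeholders:
users supply their full 25-gene list; the synthetic cohort plants its
own signature, so the benchmarks do not depend on the published list.

## Knockdown readouts

2^-ΔΔCt uses replicate-mean Ct per (condition, gene) before
differencing — the determinate, conventional aggregation; per-replicate
RQ averaging (which also yields a fold-scale dispersion) is available
via `per_replicate=True`, and the base is configurable for amplification
-efficiency corrections (default 2).  RQ is invariant to plate-wide Ct
offsets by construction.  Assay readings are divided by the
scrambled-control mean.  Heatmap matrices are exported both as RQ and
log2(RQ).

## Synthetic data: what it emulates, and what it does not

Defaults mirror the cohort structure the pipeline targets: a 152-tumor
TMA cohort (grades 9/98/42/3 for G1–G4; nuclear positivity 39.5% YAP /
31.6% TAZ, cytoplasmic 28.3% / 2.6%), a 104-tumor + 6-normal expression
cohort with a 25% high-CIN cluster, and four-condition siRNA plates.

* **TMA tables**: per-tumor positivity is Bernoulli per (marker,
  compartment), independently across markers; positive tumors draw a
  core score from a configurable distribution skewed toward low scores
  (the per-patient score distribution is a free parameter, not an
  estimate), factored uniformly into a (quantity, intensity) pair; the
  second core repeats the first with probability `core_concordance`
  (default 0.7), otherwise re-draws under the same positivity.  Marker
  co-occurrence beyond independence is not modeled.
* **Fields**: nuclei are disks, cytoplasm concentric annuli — the
  simplest geometry preserving the nuclear-subtraction logic; realism
  (irregular morphology, touching cells, 3-D structure) is a non-goal.
  Nuclei are placed without overlap by rejection sampling with a
  bounded attempt budget; exceeding it raises an error naming the
  density limit.  Pixel noise is Gaussian truncated at zero, which
  keeps intensities physical without materially changing means at the
  default SDs (5 units against compartment intensities of 100–200).
* **Expression**: per-gene baseline log2 abundance ~ N(5, 2); per-sample
  log-normal dispersion (SD 0.5 log2 units); signature genes shifted by
  `effect_log2fc` (default 3) in planted high-CIN tumors; counts are
  Poisson draws from rates scaled to a uniform library size
  (0.8–1.2 M), so CPM normalization faces genuine library-size
  variation.  Because CPM is compositional, a planted shift in a large
  signature fraction attenuates all per-gene CPM contrasts equally; the
  signature-vs-background contrast recovers the planted effect exactly,
  and the benchmarks account for this.  Batch effects and probe-level
  structure are not modeled.
* **Survival**: exponential with hazard h·exp(β·s), where s is the
  planted score (effect_log2fc for high-CIN tumors, 0 otherwise),
  h = 0.02 events/month and β = 0.3 by default (cluster hazard ratio
  ≈ 2.5, in the range reported for high-risk CCA subgroups), with
  administrative censoring at 60 months.  Closed-form and sufficient
  for calibration/power studies; non-proportional hazards are not
  modeled.
* **Plates**: residual fraction f raises the target Ct by −log2(f)
  cycles over a baseline of 24 cycles (`target_baseline_ct`; the
  reference gene sits at 18 and is condition-independent up to noise).
  The default plants combined-only repression of CIN genes (f = 0.9
  single, 0.4 combined) and all-condition repression of the direct
  targets CYR61/ANKRD1 (0.5 single, 0.25 combined).

Passing benchmarks on these cohorts demonstrates that the *procedures*
recover what was planted under the stated noise; they do not certify
performance on real tissue images (stain variability, touching cells)
or real transcriptomes (batch structure, dropout).

## Statistics

Mann-Whitney U uses average-rank ties; the exact null distribution is
used when n_a+n_b ≤ 20 and the pooled data are tie-free (auto mode),
otherwise the normal approximation with tie and continuity correction.
Spearman's r is Pearson on average ranks, p from the t approximation
with n−2 df.  All p-values are two-sided.  No multiple-testing
correction is applied anywhere — each stage reports raw per-comparison
p-values, and it is the user's responsibility to account for
multiplicity across stages.  Rank statistics, k-means and survival
machinery delegate to scipy, scikit-learn and lifelines respectively;
the test suite validates each against independent brute-force oracles
(full enumeration of U, rank-then-Pearson, normal equations, a
hand-computed product-limit table, permutation log-rank).

## Benchmark problem sizes

The shipped studies use 50 noisy 256×256-px fields for ratio recovery,
100 cohorts × 200 fields for density-effect detection, the default
104-tumor cohort for cluster recovery, 400 null cohorts for log-rank
type-I error, and 200 two-arm cohorts (52/group, hazard ratio 2.5) for
power — sizes at which the binomial/Monte-Carlo error of each reported
rate is small relative to the property being checked.

## Interfaces

The library is the interface: every operation is a plain function over
pandas/numpy containers, the `analysis/` drivers are thin narrative
scripts over it, and `ccapipe.pipeline.run_pipeline` orchestrates all
stages from a validated configuration (unknown keys rejected; every
output carries a provenance header with tool version, seed and config
hash; reruns at a fixed seed are byte-identical).  Tables are UTF-8
TSV/CSV, nested results JSON, images 2-channel 16-bit TIFF, masks 8-bit
0/255 TIFF.
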