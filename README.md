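# ccapipe

Analysis pipeline for studying the Hippo-pathway co-activators YAP and
TAZ in cholangiocarcinoma (CCA)-style cohorts.  It covers the four
computational stages such a study runs, each exercisable end-to-end on
synthetic data with known ground truth:

1. **IHC scoring** (`ccapipe.ihc`) — semiquantitative scoring of
   tissue-microarray cores and marker positivity cross-tabulation.
2. **Subcellular localization** (`ccapipe.ifquant`) — nuclear-to-
   cytoplasmic (n/c) fluorescence-ratio quantification per imaging field
   and its dependence on cell density.
3. **CIN25 signature** (`ccapipe.cin`) — chromosomal-instability
   gene-signature scoring, k-means clustering and Kaplan-Meier/log-rank
   survival stratification.
4. **Knockdown readouts** (`ccapipe.assays`) — relative expression after
   siRNA silencing by the 2^-ΔΔCt method and fold-of-control assay
   normalization.

`ccapipe.synthetic` generates all four input families (TMA scoring
tables, two-channel fluorescence fields, expression cohorts with
survival, qPCR plates) with planted ground truth, so every stage has a
parameter-recovery benchmark (`ccapipe.evaluation`).  It is aimed at
computational pathology / tumor-biology groups who want these standard
analyses as tested, scriptable building blocks rather than spreadsheet
conventions.

## The core quantities

**IHC score.** Each core is coded by quantity q ∈ {0..4} (fraction of
positive cells) and intensity i ∈ {0..3}; the core score is the product
q·i ∈ {0,1,2,3,4,6,8,9,12} and the tumor score the arithmetic mean of
its two cores.  Scores ≤ 3 are low/no expression, 3.5–7.5 intermediate,
≥ 8 high.  A tumor is called positive when its mean score exceeds a
configurable threshold (default: any staining, score > 0).  The
cross-tabulation reports, per compartment, counts positive for each
marker, for *exactly one* marker (YAP + TAZ − 2·both) and for *both*.

**n/c ratio.** Per field, nuclei are segmented from the DAPI channel
(Gaussian smoothing, Otsu threshold, minimum-area filter), the cell
region from the stain channel, and the cytoplasm is the cell region
minus the nuclei.  The ratio is mean nuclear / mean cytoplasmic stain
intensity; fields are split into low/high density at the mean nucleus
count over all fields.

**CIN25 score.** With x_gs the log2(CPM+1) expression of gene g in
sample s, the signature score is

    score(s) = Σ_g (x_gs − mean_g) / sd_g     over the signature genes,

so each gene contributes equally; scores sum to zero over the scaling
population.  Samples are clustered by k-means (k = 3) on the per-gene
scaled signature submatrix, or dichotomized at the median score, and
groups are compared by the log-rank (Mantel-Cox) test.

**2^-ΔΔCt.** Per condition, ΔCt = mean Ct(target) − mean Ct(reference
gene); ΔΔCt = ΔCt(condition) − ΔCt(scrambled control); relative
expression RQ = 2^-ΔΔCt.

All group comparisons use the Mann-Whitney U test, associations
Spearman's rank correlation; p-values are two-sided and uncorrected.

## Worked example

The numbered drivers under `analysis/` run each stage on synthetic
inputs and print what they find; `analysis/00_demo_pipeline.py` runs
everything at once.  For instance:

```sh
$ python analysis/04_cin_survival.py --seed 0
k-means (k=3) cluster sizes: {1: 36, 2: 26, 3: 48}
Planted high-CIN cluster recovery: ARI = 1.00, captured 100% of planted members, prevalence 25.0% of tumors (planted 25%)
Median-split survival: log-rank chi2 = 0.89 (df=1), p = 0.344 ns
Cluster-split survival (top-score cluster vs rest): log-rank chi2 = 10.71, p = 0.00107 **
Stratification operating characteristics: type-I error 0.052 (nominal 0.05, 400 null cohorts); power 0.97 at hazard ratio 2.5 with 52/group
```

The 104-tumor synthetic cohort plants a high-CIN cluster in 25% of
tumors with shorter survival; k-means on the scaled signature submatrix
recovers that cluster exactly (adjusted Rand index 1.0, one 26-sample
cluster), and stratifying survival by that cluster separates the groups
(p ≈ 0.001).  The median split halves the cohort and therefore dilutes
a 25%-prevalence effect on this seed — the operating-characteristics
lines quantify that the log-rank machinery itself is calibrated (type-I
error ≈ 0.05) and well powered at the planted hazard ratio.

Similarly, `analysis/02_ihc_positivity.py` recomputes the reference
cross-tabulation rows from marginal counts (e.g. the intrahepatic
nuclear row: YAP 39.5%, TAZ 31.6%, exactly one 43.4%, both 13.8%), and
`analysis/03_density_shuttling.py` recovers a planted n/c ratio of 2.0
to within 4% through full segmentation and detects a planted density
effect in 100/100 cohorts.

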