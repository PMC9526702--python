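# nichedeconv

Histomorphologic **niche deconvolution** of bulk glioblastoma proteomes.

Glioblastoma tissue is a mosaic of five hallmark histomorphologic niches —
leading edge (LE), infiltrating tumor (IT), cellular tumor (CT),
microvascular proliferation (MVP), and pseudopalisading cells around
necrosis (PAN). Bulk proteomic profiles of tumor specimens mix these niches
in unknown proportions, which confounds comparisons across the
transcriptional subtypes (proneural, classical, mesenchymal). `nichedeconv`
estimates the relative niche contributions of each bulk sample from a
random forest trained on niche-labelled reference profiles of
microdissected regions, and then asks whether niche-dominant labels are
enriched in particular subtypes.

## Method

Given a reference atlas of microdissected regions with niche labels and a
bulk cohort measured on a different quantification scale:

1. **Preprocessing** (Perseus-style): keep proteins quantified in ≥ 60% of
   the samples of at least one annotation group; log2-transform raw
   intensities; impute missing (left-censored) values per sample from a
   downshifted Gaussian, `N(m − downshift·s, (width·s)²)` with the sample's
   observed moments `(m, s)`; intersect features across datasets; z-score
   each sample so LFQ-like and TMT-like scales become comparable.
2. **Classification**: a forest of 200 Gini decision trees (bootstrap,
   √p features per split) grown on the reference regions, with node
   expansion stopped once a node's majority class reaches 95%. An 80/20
   split stratified by niche (keeping technical duplicates of a region in
   the same fold) provides a confusion matrix and macro one-vs-rest ROC AUC.
3. **Deconvolution**: for a bulk sample *j*, the estimated abundance of
   niche *g* is the fraction of trees voting *g*,
   `p_j(g) = #{trees voting g}/200`, a point on the 4-simplex. The niche
   with the greatest vote fraction is the sample's dominant "…-like
   signature" (ties broken LE < IT < CT < MVP < PAN).
4. **Cohort statistics**: S0-moderated differential test
   `t_s0 = (x̄_A − x̄_B)/(s_pooled·√(1/n_A + 1/n_B) + s0)` with
   permutation-based FDR (group-label shuffles, median exceedance count over
   the observed count along the cutoff curve); one-tailed Welch contrasts
   with Benjamini–Hochberg correction; Pearson χ² of subtype × dominant
   niche with a 2×2 focus collapse; PCA; 1 − Pearson-r average-linkage
   clustering; Spearman correlation of group-averaged profiles.

A synthetic-data generator produces reference atlases and bulk Dirichlet
mixture cohorts with known ground truth (niche marker effects, patient
random intercepts, technical duplicates, intensity-dependent censoring,
cross-platform affine shift, subtype–niche coupling), so the whole pipeline
is testable without any external downloads. Real matrices can be supplied
as TSV or GCT 1.2 via `nichedeconv ingest`.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables to `results/pipeline/`:

```sh
python analysis/01_simulate.py          # atlas (156 columns) + bulk (n = 110)
python analysis/02_preprocess.py        # 4794 -> 4452 proteins, 74787 cells imputed
python analysis/03_train_classifier.py
python analysis/04_deconvolute.py
python analysis/05_subtype_enrichment.py
python analysis/06_differential_volcano.py
```

Representative output (master seed 7):

```
held-out macro one-vs-rest AUC = 1.0000 (28 test columns, 128 train)
dominant-niche accuracy (true weight >= 0.6): 1.000 (52 samples)
Spearman(pred prob of true dominant niche, true weight) = 0.972
subtype x dominant-niche chi2 = 58.50 (df 12, p = 4.24e-08)
focus ('proneural', 'IT'): chi2 = 19.62, p = 9.42e-06
IT markers, proneural > mesenchymal: median q = 4.14e-06, fraction BH-significant = 1.00
IT markers, proneural > IDH-mutant: median q = 0.951, fraction BH-significant = 0.00
randomized split (50 vs 50): 1 significant proteins
niche-stratified (IT n=37 vs MVP n=31): 311 significant proteins
```

Read: the classifier separates held-out reference regions essentially
perfectly; bulk samples dominated (weight ≥ 0.6) by one niche are called
correctly; IT-like dominant labels are strongly enriched among proneural
tumors; the IT marker proteins are elevated in proneural versus mesenchymal
and classical tumors but not versus the IDH-mutant group (which shares the
infiltrative mixture tilt — a designed null contrast); and a random split
of the cohort yields an empty volcano while stratifying the same samples by
dominant niche recovers hundreds of differential proteins.

The same pipeline is scriptable via the `nichedeconv` CLI
(`simulate`, `preprocess`, `train`, `deconvolute`, `stats …`, `run`,
`ingest`) — see `nichedeconv --help`.

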