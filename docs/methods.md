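# Methods

## The model

`nichedeconv` treats bulk-tumor niche estimation as multiclass
classification with a compositional readout. A random forest is trained to
recognize the five glioblastoma niches (LE, IT, CT, MVP, PAN) from
z-scored protein profiles of microdissected reference regions. Applied to a
bulk sample, each of the 200 trees casts one hard vote; the vote fractions
are reported as the sample's niche composition. Because the votes partition
the forest, the estimate lies on the 4-simplex by construction and needs no
renormalization. The vote fraction is a relative, model-referenced
abundance — it is not calibrated to physical tissue-area fractions, and no
alternative regression-style deconvolution backend (NNLS / support-vector
regression) is provided.

Assumptions: (i) each niche has a reproducible protein signature that
survives per-sample z-scoring; (ii) a bulk profile is approximately a
convex combination of niche profiles on the scale the classifier sees
(log-intensity, then z-score); (iii) the reference atlas and the bulk
cohort share enough quantified proteins that the intersected feature set
still carries the signatures.

### Purity-stopped trees

Tree growth is depth-unlimited but a node stops splitting once its majority
class reaches `purity_stop` (default 0.95) of the node's samples. This is
implemented as an exact post-hoc truncation of fully grown scikit-learn
trees: greedy induction chooses each split only from the data reaching that
node, so cutting the tree at the first node meeting the purity threshold
yields the same predictions as stopping growth there. The stub's vote is
its majority class, ties resolved in canonical niche order. Trees use Gini
splits, bootstrap resamples, and √p candidate features per split.

### Train/test protocol

The 80/20 split is stratified by niche, with ⌈0.8·n⌉ units per niche in
training. The splitting unit defaults to the microdissected *region*, so
technical duplicates of one region never straddle the fold boundary
(avoiding leakage that would inflate held-out metrics); `split_by="sample"`
overrides this. Evaluation reports the 5×5 confusion matrix of dominant
calls and the macro-averaged one-vs-rest ROC AUC of the vote fractions;
a single AUC for a 5-class problem requires an averaging convention and
macro one-vs-rest was chosen as the most common one. Both single-split and
repeated-split (loop over seeds) use are supported by the API; the bundled
analysis reports a single seeded split.

## Preprocessing

* **Presence filter**: a protein is kept iff its non-missing fraction is
  ≥ `min_frac` (default 0.6, inclusive boundary) within at least one
  annotation group. The operation is idempotent.
* **log2**: applied only to matrices tagged `raw`; non-positive intensities
  are an error naming the offending protein/sample.
* **Imputation**: missing values in sample *j* are drawn from
  `N(m_j − downshift·s_j, (width·s_j)²)` using the sample's observed
  moments (`scope="per_sample"`, the column-wise convention; `"global"`
  uses matrix-wide moments, and a sample with < 2 observed values falls
  back to global moments with a warning). Defaults are
  `downshift=0.3, width=1.8`; the transposed pair `downshift=1.8,
  width=0.3` — the conventional Perseus default — ships as
  `ImputationParams.perseus_convention()` / `--perseus-convention`. The two
  parameterizations are plausibly swapped in parts of the literature, so
  both are first-class and the tests cover both.
* **Harmonization**: after feature intersection, every sample column is
  standardized to mean 0, SD 1 (denominator n − 1 throughout). Both the
  reference and the bulk matrix are z-scored by default so training and
  application scales match; z-scoring the reference can be skipped, but
  then the cross-platform shift is uncorrected. Feature matching is exact
  and case-sensitive; when both datasets carry `;`-separated multi-id
  strings, only the leading id is compared.

A `scale_tag` on every matrix (`raw → log2 → log2-imputed → zscored`)
enforces pipeline order; e.g. z-scoring a matrix that still has missing
values is rejected rather than silently propagating NaNs.

## Cohort statistics

* **S0 volcano**: `t_s0 = (x̄_A − x̄_B)/(s_pooled·√(1/n_A+1/n_B) + s0)`
  with `s0 = 0.1` by default (a Welch denominator is available by flag).
  At `s0 = 0` the statistic is exactly the pooled two-sample t.
  Significance is permutation-based: scanning cutoffs along the observed
  |t| values, the FDR at a cutoff is the median count (over group-label
  shuffles, default 250) of permuted statistics exceeding it divided by
  the observed count; the most permissive cutoff with FDR ≤ the target
  (default 0.05) defines the significant set. With no qualifying cutoff
  nothing is called. Nominal t p-values are attached for plotting only.
* **Marker contrasts**: one-tailed Welch t-tests (the direction is a
  required argument, never inferred) with Benjamini–Hochberg q-values.
  Proteins with zero variance in both groups and zero difference get the
  continuity value p = 0.5, logged.
* **χ² enrichment**: Pearson χ² (no continuity correction; Yates available
  for the 2×2) of the subtype × dominant-niche table, with an optional 2×2
  focus collapse (focus subtype vs rest × focus niche vs rest). Expected
  cells < 1 trigger a warning, not an automatic fallback. Normal-brain
  controls are excluded from the bundled enrichment analysis because they
  are LE-dominant by construction and would mimic dependence.
* **PCA / clustering / Spearman**: samples-as-observations PCA with
  per-protein centering and a deterministic sign convention (largest-|loading|
  protein positive); 1 − Pearson-r distances with average linkage; Spearman
  correlation (average-rank ties) of group-averaged protein vectors between
  feature-intersected datasets.

## The synthetic study

The generator emulates the structure of a microdissected reference atlas
and a bulk proteogenomic cohort. Default conditions, chosen once as a
realistic desk-scale stand-in:

| parameter | default | rationale |
|---|---|---|
| proteins | 4794 | scale of a deep tissue LFQ experiment |
| patients × regions × duplicates | 20 × 78 × 2 = 156 columns | not every patient yields every niche |
| markers per niche / effect | 150 / 3.0 log2 | strong niche markers are ~8-fold enriched |
| patient SD / residual SD | 0.5 / 0.5 log2 | biological vs technical spread |
| censoring | 10% of a noisy intensity proxy (SD 0.5) below the matrix-wide quantile | left-shifted MNAR missingness |
| bulk cohort | n = 110; 22/26/38/14/10 proneural/classical/mesenchymal/IDH-mutant/normal | representative subtype mix |
| mixtures | Dirichlet α = 0.5; coupling ×4 for proneural→IT, IDH-mutant→IT, mesenchymal→MVP; normals = pure LE | spread of dominant weights plus subtype tilts |
| platform shift | 0.8·x + 5 | makes z-score harmonization matter |

Mixing acts on log-scale profiles (weighted arithmetic mean of
log-intensities) rather than linear intensities: the classifier consumes
log/z-scored data, so the mixture is defined on the scale the model sees.
The IDH-mutant group is coupled to IT deliberately so that
proneural-vs-IDH-mutant marker contrasts act as a designed null. Censoring
uses a noisy proxy drawn independently of the quantile, making the missing
set monotone in the quantile at a fixed seed. Bulk (TMT-like) matrices are
generated complete, as isobaric-label cohorts have little missingness.
If the subtype counts do not sum to a requested `n_bulk`, they are rescaled
by largest-remainder rounding.

What the generator does **not** emulate: raw spectra, peptides, protein
inference, correlated protein modules, batch effects beyond a global affine
shift, or niche profiles that drift between the atlas and the bulk cohort.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the stated generative assumptions — not classification
performance on real tumors, where signatures are weaker and platform
differences are not affine.

## Numerical choices and degeneracies

* All randomness flows from explicit integer seeds; pipeline stages derive
  seeds as truncated SHA-256 of `(master_seed, stage_name)` (< 2³¹), so
  stages are independently reproducible.
* Dominant-niche ties break by the canonical order LE < IT < CT < MVP <
  PAN (first maximum).
* Per-niche AUC is undefined (NaN, excluded from the macro mean) when a
  class is absent from the test set; the stratified splitter prevents this
  in normal use.
* A Dirichlet concentration of ∞ for a niche collapses the mixture to
  weight 1 on that niche (first such niche in canonical order).
* TSV round-trips write 17 significant digits, preserving doubles exactly;
  empty cells encode missing values.

## Analysis problem sizes

The bundled analysis and the acceptance script run the default study
(4794 proteins, 156 reference columns, 110 bulk samples), 100 replicate
cohorts each for enrichment power and null calibration, 20 null volcano
simulations at 5000 proteins × 40 samples with 250 permutations, and one
50-protein spike-recovery simulation. These sizes give stable Monte-Carlo
estimates (binomial SE ≤ 5 percentage points on rates) while completing in
well under a minute.

## Known limitations

* Vote fractions are bounded away from 0/1 only by forest diversity; they
  are not calibrated probabilities, and compositions for mixtures far from
  any training profile are extrapolations.
* The permutation-FDR estimator is the median-count variant; with few
  permutations (< 1/FDR) its resolution is coarse and a warning is issued.
* The Pearson χ² focus test can be mildly anticonservative at small
  expected counts; the expected-cell warning flags this, and an exact test
  is deliberately not substituted automatically.
* Real-data ingestion handles plain TSV/GCT matrices only; search-engine
  output parsing beyond that is out of scope.
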