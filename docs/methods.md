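# Methods

This note documents the models, procedures and numerical choices behind
`atlasbench`, in the package's own words: what each component assumes, which
parameters matter, and what the bundled synthetic data can and cannot show.

## Data model and preprocessing

The benchmark's unit of work is a `SplitDataset`: a reference (the
multi-batch dataset an atlas embedding is built from) and a query (held-out
batches mapped into that embedding afterwards), sharing an identical,
identically ordered feature list, plus the set of *unseen labels* — query
populations deliberately removed from the reference so that
unseen-detection metrics have a ground truth. Counts are stored cells ×
features everywhere; every per-cell vector is row-aligned with the counts.

`prepare_split` applies, in order:

1. **Cell quality control** — cells with fewer than 100 total counts or
   fewer than 100 detected features are removed (`min_counts`,
   `min_features`).
2. **Split** by batch into reference and query.
3. **Small-label removal** — labels with fewer than 20 cells
   (`min_label_cells`) are removed, applied per half independently. The
   per-half application is deliberate: unseen labels exist only in the
   query, so a single joint filter is not well defined. A label may
   therefore survive in one half only.
4. **Unseen-label removal** from the reference only.
5. **Feature filter** — features not expressed (count > 0 in ≥ 1 cell) in
   the reference are dropped from both halves.

The provenance dict records the cells/features removed at every stage, so
`cells_in = cells_out + cells_removed` holds per stage, and the whole
procedure is idempotent. Filter order matters (a cell failing QC could
otherwise rescue a small label); the order above is fixed.

## Synthetic benchmark

### Count-level simulator

`simulate_counts` is a splat-style hierarchical Poisson–gamma model:

- gene base means ~ Gamma(shape 0.6, rate 0.3);
- per-label differential expression: each gene is DE with probability
  `de_prob` and receives a multiplicative log-normal(0, `de_scale`) factor
  (ground-truth flags *and* factors are kept in provenance);
- per-batch multiplicative log-normal(0, `batch_effect_sd`) gene factors;
- optional per-cell × per-gene log-normal(0, `label_noise_sd`) noise
  applied before count sampling — extra within-label variability beyond the
  negative-binomial mean–variance relation;
- library sizes ~ log-normal(`lib_loc` = 9, `lib_sd` = 0.25) scaled by the
  batch's `depth_factor`; the expected count of gene g in cell c is
  `L_c · m_g(c) / Σ_g m_g(c)`;
- counts ~ Poisson(Gamma) with biological coefficient of variation `bcv`
  (default 0.2), i.e. negative binomial with dispersion `bcv²`;
- an optional trajectory: cells of a branch label sit at a uniformly drawn
  step `t ∈ {1..n_steps}/n_steps` and their mean profile interpolates
  log-linearly between the progenitor's and the branch terminal's profile.
  The step is metadata; the cell's label is the branch name, because all
  metrics are label-based.

The distributional form of the label-specific noise (log-normal
multiplicative) is this package's choice; it is documented as such and not
claimed to match any external simulator. The simulator makes no attempt at
doublets, ambient RNA, cell-cycle effects, zero inflation beyond the NB, or
real gene identities — conclusions drawn from it say that the pipeline
machinery behaves correctly, not that a method will behave identically on
tissue data.

The bundled scenario (`splat_scenario`) mirrors a design with three
"technologies" of two batches each — medium cells/medium depth, few
cells/high depth (3×), many cells/low depth (0.3×) — with the low-depth
pair as query, ten labels including a progenitor with two branches, and
"Rare", "Perturbed" and "Intermediate" (a trajectory branch) as query-only
unseen populations. `scale` multiplies all cell numbers; tests and the
acceptance script run at `scale` 0.12–0.25 (roughly 250–500 cells), a size
chosen so the full pipeline runs in seconds while every metric still has
enough cells to be defined.

`simulate_counts` returns a `SplitDataset` by routing the assembled matrix
through `prepare_split` with the QC thresholds disabled — the simulator
controls its cell counts; QC is for real data — so the split invariants
hold by construction.

### Embedding-level generator and fixture integrator

`simulate_embedding` skips counts entirely: cells are drawn from Gaussian
label clusters (`cluster_sd`) at centers placed with a minimum separation,
each batch offset by a Gaussian vector of scale `batch_shift_sd`, query
batches by an extra `query_shift_sd`, and unseen labels placed either
≥ 6·`cluster_sd` from every center ("far") or exactly on one ("merged").
It exists to give metric tests instances whose right answer is known by
construction.

`fixture_integrate` stands in for a real integration model so that metric
*responsiveness* is testable: log1p counts-per-10k → PCA fit on the
reference (query projected in) → each batch mean pulled toward the global
mean by the fraction `removal`. `removal = 0` is exactly the uncorrected
PCA (kept as `pre_integration`); `removal = 1` centres every batch. It
removes only mean shifts — deliberately: a one-dial integrator whose
batch-centroid separation is provably monotone in the dial. It is not an
integration method and is never a fair comparison point for one.

## Feature selectors

Simple selectors rank raw statistics (`high_mean`, `high_variance`,
`low_variance` as the stable-expression negative control, `random`, `all`).
Two HVG recipes are provided:

- `hvg_binned_dispersion` — dispersion (variance/mean) of counts-per-10k,
  log-transformed, z-scored within 20 equal-width bins of log1p mean
  expression (the classic dispersion flavor). An earlier variant computing
  dispersion on log1p values recovered distinctly fewer ground-truth DE
  genes in simulation and was discarded in favor of this standard form.
- `hvg_vst` — a degree-2 polynomial of log10 variance on log10 mean of raw
  counts predicts each gene's expected standard deviation; counts are
  standardised by it, clipped at √n_cells, and genes ranked by the variance
  of the standardised values.

`select_batch_aware` runs a selector per batch and combines by (number of
batches selecting the feature, then median within-batch rank, then feature
id) — features consistently chosen across batches win.

`wilcoxon_markers` is the one supervised selector: per label, a Wilcoxon
rank-sum test of each feature (label vs rest, on log1p counts-per-10k),
dropping features expressed in < 10% of the label's cells, in > 80% of
cells outside it, or with p > 0.1; survivors are sorted by estimated log
fold change (log2 of mean normalised expression ratio with pseudocount
1e-9) and the top 200 per label kept. Per-label sets are combined by
**union** by default: the intersection of per-label marker lists is
generically empty, which cannot be what a well-performing method computes;
both rules are exposed. Raw p-values are used (no multiplicity correction)
— the threshold is a filter, not an inference.

## Label transfer

A multinomial logistic regression (lbfgs, L2 with C = 1.0, tol 1e-6, max
1,000 iterations) is fit on the reference embedding coordinates against the
ground-truth labels; query cells receive the full softmax probability
vector and the argmax label. Classes are ordered lexicographically and
argmax ties resolve to the first class, making predictions deterministic.
The regularisation is fixed rather than tuned: the classifier is part of
the measuring instrument, and a fixed instrument is comparable across
methods.

## Metrics

Defaults live in `MetricConfig`; the important ones: LISI perplexity 30,
kNN graph size 90, CMS k = 75 and α = 0.1, Mahalanobis boundary quantile
0.90, minimum query-label size 20, Leiden resolutions 0.1–2.0 in steps of
0.1, covariance shrinkage ε = 1e-6, ldfDiff bound u = 1.0, Milo FDR 0.1
with k = min(5·n_batches, 200) and index subsampling at
max(20,000, 10% of cells).

Numerical choices that had to be pinned down:

- **LISI** is distance-based with perplexity-calibrated Gaussian weights
  over the 3·perplexity nearest neighbors (bandwidth by bisection to
  entropy log perplexity), not a graph-based variant — fully specified and
  checkable against brute force. With fewer cells than the window the
  perplexity is reduced with a warning.
- **Quantiles** use linear interpolation (numpy default, type 7);
  boundary comparisons are strict (>). This makes the self-map property
  exact: with n = 200 cells per label, the 90th-quantile boundary leaves
  exactly 20 cells strictly outside, so a query that copies the reference
  scores 0.900.
- **Covariance shrinkage** `Σ + ε(trΣ/d)I` plus pseudo-inverse keeps small
  labels usable at d = 10–30 without changing well-conditioned cases.
- **bNMI** weights each cell `1/(B·n_batch(cell))` in the contingency
  table (equal total weight per batch) and normalises mutual information
  by the arithmetic mean of entropies; it reduces to plain NMI for
  equal-sized batches, which is the cross-check used in tests.
- **Clustering sweep** ties resolve to the lowest resolution; Leiden is
  seeded. Isolated-label F1 searches all resolutions and clusters, not
  just the best clustering.
- **ldfDiff** densities are inverse mean kNN distance; the local density
  factor is a cell's density over its neighbors' mean density, computed
  within the cell's own batch in the pre-integration space and in the full
  integrated space. The cap u = 1 (one log2 unit) bounds the influence of
  any single cell.
- **Milo engine**: per neighborhood, batch-level member counts are
  regressed on the batch's query indicator with a log batch-size offset
  under a negative binomial whose dispersion is a single moment estimate
  shared across all neighborhoods (pooled Pearson residuals under the
  closed-form per-arm Poisson fit). The Wald test is one-sided (query
  enrichment); completely separated neighborhoods (one arm all zero) and
  degenerate fits fall back to an exact one-sided binomial test.
  Neighborhoods are attributed to the majority member label, ties to the
  index cell's label. This preserves the published contract (inputs, k,
  subsetting, FDR, scoring) while replacing the delegated statistical
  engine with an explicit, testable one.
- **Mapping and unseen distance metrics use ground-truth query labels**,
  not transferred ones: they measure the mapping; transferred labels are
  scored separately by the classification metrics.
- **Rarity weighting** is `w_l ∝ 1/n_l` over true query class counts —
  an explicit definition of "rare classes matter more".
- **Batch PCR** runs in comparison mode (pre vs post) whenever a
  pre-integration embedding exists and falls back to `1 − PCR_post`
  otherwise; the mode is recorded in the score's notes.

## Scaling, aggregation, ranking, profiling

Per (dataset, metric), raw scores are rescaled linearly by the min/max over
four baseline feature sets: all features, batch-aware dispersion-HVG
(n = 2,000), random (n = 500, scores averaged over five seeds), and a
stable/low-variance negative control (n = 200). On small synthetic
instances these sizes shrink proportionally (n/2, n/4, n/8, capped at the
full-scale values) so the baselines remain distinct sets. Scaled values are
*not* clipped — above 1 means better than every baseline, below 0 worse.
Categories are averaged (missing values excluded with a note) and combined
as

    Overall = 1/2 (Int.Batch/2 + Int.Bio/2)
            + 1/2 (Mapping/3 + Class/3 + Unseen/3)

equivalently weights (¼, ¼, ⅙, ⅙, ⅙): equal importance to building the
reference and to using it. Ranks are descending with ties averaged;
cross-dataset ranks are means of per-dataset ranks. `standardize` z-scores
values within (dataset, method) groups using the sample (n−1) standard
deviation, mapping constant groups to 0. `profile_metrics` computes, per
metric, the observed range over random feature sets, the Pearson
correlation with the number of features over ordered (HVG-ranked) sets,
correlations with supplied technical factors, and the inter-metric
correlation matrix — a metric with zero observed range cannot distinguish
feature sets and is a candidate for exclusion.

## Reproducibility

Every stochastic component takes a seed; the pipeline derives all stage
seeds from one master seed by fixed offsets, and rerunning with the same
configuration reproduces all tables bit-identically. One caveat: the
Milo-style score's index-cell subsampling is seeded by configuration, not
by cell identity, so it is permutation-invariant only when the subsample
covers all cells (always the case below 20,000 cells, including every
bundled scenario).

## Known limitations

- The fixture integrator removes only batch mean shifts; metrics'
  responses to non-linear batch effects are exercised only through the
  embedding-level generator.
- The CMS p-values come from the Anderson–Darling k-sample approximation,
  whose tail probabilities are interpolated; calibration at α = 0.1 is
  accurate to a few percent, which is the tolerance used in tests.
- The Milo-style score's shared-dispersion NB Wald test is an
  approximation to a full count-model pipeline; its null behavior is
  verified empirically (score ≈ 0 on resampled pseudo-unseen labels) but
  small-sample p-values are not exact.
- The kNN-correlation and unseen-uncertainty metrics are computed but
  excluded from category means by default, mirroring the final selected
  panel.
- Scores on the scaled-down synthetic scenario demonstrate correctness of
  the machinery, not feature-selection recommendations: with a few hundred
  features, selecting features cannot help much over using all of them.
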