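# Methods

This note documents the models and procedures implemented in `trgkit`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## TRG classification

A gene is called **taxonomically restricted** when (a) it has no homology
hit to a taxon outside the focal lineage with E-value < `e_max` (default
10⁻⁶, strict inequality) covering more than `min_cov` (default 0.30,
strict) of the *query* protein length, and (b) it encodes no annotated
protein domain. Choices behind this:

* **Coverage denominator is the query length.** The focal proteome is the
  object being classified; using subject length would make the call depend
  on the hit database's gene models. This is flagged as a genuinely open
  reading of "30% of the protein length".
* **Within-lineage hits never disqualify.** Self-hits and paralogs are
  expected and uninformative for taxonomic restriction.
* **Domain exclusion relabels as shared.** A would-be TRG carrying a known
  domain is counted with the shared genes, but keeps a
  `trg_excluded_by_domain` flag because its final class is genuinely
  ambiguous.
* **Genes with no hits at all are TRG candidates**, not errors — short or
  low-complexity proteins can legitimately have no database hits.
* E-values of exactly 0 (reported by BLAST for overwhelming matches) are
  clamped to 10⁻¹⁸⁰ before −log₁₀ in best-hit profiles; genomes with no
  hit are reported at 0 (an E = 1 floor).

The `relaxed_scan` operation re-runs the out-of-lineage matching over a
grid of relaxed (coverage, E) cutoffs and reports the fraction of TRGs
still unmatched; by the subset relation of qualifying hits this fraction
is non-increasing along each axis.

## Statistical primitives

All two-sample tests return a common `TestResult`. Conventions:

* **Wilcoxon rank-sum.** Statistic is W, the midrank sum of the first
  sample. For n₁+n₂ ≤ 12 the p-value is exhaustive enumeration over all
  C(n₁+n₂, n₁) rank assignments (exact even with ties; the enumeration
  cost is at most 924 combinations). Above that, normal approximation
  with tie-corrected variance and a 0.5 continuity correction. Two-sided
  exact p is min(1, 2·min(P(W′≤W), P(W′≥W))).
* **Kolmogorov–Smirnov.** D is the sup of the ECDF difference over data
  points; p uses the asymptotic Kolmogorov distribution at √(n_eff)·D
  with n_eff = n₁n₂/(n₁+n₂). No small-sample exactness is attempted; at
  n = 30 per arm the realized size is ≈ 0.035 at nominal 0.05 (slightly
  conservative), verified by simulation in the test suite.
* **χ² on 2×2 tables** without continuity correction by default (a
  `correction` flag provides Yates); zero margins are errors naming the
  empty margin.
* **t-test is Welch's** (unequal variances, Welch–Satterthwaite df).
  "t-test" alone underdetermines the variant; Welch is the safer default
  and reduces to Student under equal variances.
* **Hypergeometric enrichment** is the upper tail P(X ≥ k), computed in
  log space (scipy); it agrees with exact rational-arithmetic summation
  to 10⁻¹² for all universes up to N = 30 in the tests.
* **Alternatives default to two-sided** everywhere; the directional
  choice is configurable but the analyses report two-sided values.
* Correlations on zero-variance vectors propagate as missing (NaN),
  never silently as 0, so downstream averages can skip them.

## Coexpression features

Per (target, gene) pair and dataset: Pearson r over samples, clamped to
±0.999999 before the Fisher transform to avoid infinities, then z
averaged across the datasets where both genes are present with variance.
Pathway features average those per-pair means over member genes.

* **Averaging order is per-pair-first, then per-pathway.** The alternative
  (pathway average per dataset, then across datasets) differs when genes
  are missing from some datasets; the per-pair order weights every
  (dataset, member) observation of a pair equally and is guarded by a
  regression test (duplicating a dataset whose z equals the existing mean
  moves no cell).
* **The target is excluded from pathways containing it** — self-correlation
  is uninformative and would inflate its own feature.
* Cells supported by fewer than `min_support = 3` (dataset × member)
  observations are reported missing; single-observation cells are noise.
* Multi-probe genes must be collapsed to one row per gene before entry;
  the reader collapses duplicates by per-dataset mean.

## Essentiality classifier

Penalized logistic regression with the elastic-net penalty at α = 0.5,
fit by cyclic coordinate descent with soft-thresholding on the IRLS
quadratic majorization (the standard glmnet scheme): features are
standardized internally, the intercept is unpenalized, coefficients are
reported on the original scale, and convergence is declared when no
coefficient moves more than 10⁻⁷. IRLS weights are floored at 10⁻⁵; on
separable data at λ → 0 a divergence guard caps iterations and warns.
Verified limits: λ = 0 matches an independent Newton/IRLS
maximum-likelihood fit to 10⁻⁶ per coefficient; λ = 10⁶ yields the
intercept-only model at logit(class rate); pure-ridge and pure-lasso fits
match independent smooth/split-variable optimizer oracles in penalized
objective to 10⁻⁸.

Cross-validation: stratified, seeded 5-fold; the λ grid is 50 log-spaced
values from λ_max (the smallest λ with all-zero coefficients) down four
decades; out-of-fold scores are **pooled into one ROC per λ** rather than
averaged per fold — with very few positive cases (essential TRGs are ~3%
of TRGs) per-fold AUCs are unstable or undefined. `cv_auc` is the maximum
over the grid and `chosen_lambda` the argmax (ties to the larger λ).
Because of the max over the path, the null distribution of `cv_auc` on
label-independent features is centered slightly above ½ and is wide when
positives are rare; null calibration is therefore asserted on the mean
across seeds. Missing feature cells are imputed to the column mean, and
the imputation is recorded alongside the coefficients.

Single-feature importance fits one univariate unpenalized logistic model
per feature with the same folds and reports its pooled CV AUC, sorted
descending with ties in stable column order.

## Genomic context

* **Neighbors are positional**, ordered by start coordinate per
  chromosome, strand ignored (operon-rich genomes make strand-aware
  ordering ambiguous); ties broken by end then identifier. Offsets 1–3
  pool the upstream and downstream gene at each distance; chromosome ends
  contribute fewer values, never wraparound.
* **Chromatin windows are gene body ± flank** (default 5000 bp), clipped
  at zero. The alternative reading — a fixed-width window centered on the
  gene — is available by setting the flank relative to a point locus, but
  body ± flank is the primary definition.
* The window statistic is the **overlap-weighted median** of interval
  values, weights in bases; an even split takes the mean of the two
  bracketing values. Genes whose window overlaps no interval are missing
  and are excluded from group tests.

## Network analysis

MCL on the adjacency with self-loops of weight 1 (standard practice;
only the inflation factor, 1.5, is a primary setting), column-normalized
to stochastic. Each iteration: expand (matrix square), inflate
(entrywise power, renormalize), prune entries below 10⁻⁵ and renormalize
— pruning keeps dense-matrix runs fast and was verified not to change the
partition on fixtures up to a few hundred nodes. Convergence when the
matrix changes by < 10⁻⁸; column sums stay within 10⁻¹² of 1 throughout
(asserted). Clusters are read from attractor rows (positive diagonal
mass); attractors that attract each other are merged; every node joins
the attractor holding the largest share of its column, ties to the lowest
cluster id. Isolated nodes would form singletons. Cluster ids are dense
from 1 in decreasing size order.

Enrichment tests every cluster with at least 31 members (">30" read as
≥ 31) with the hypergeometric upper tail against the clustered-node
universe; the Bonferroni factor is the number of clusters tested.
Degree comparisons count distinct neighbors and include only genes with
at least one interaction.

## Group comparisons

Disorder uses the externally predicted ordered fraction per protein (the
disorder and coiled-coil predictors themselves are inputs, not part of
this package); classes are compared by KS. Coiled-coil presence is a 2×2
χ² per contrast. The dN/dS report tests each functional class against
**all** genes with Welch's t — the class deliberately included in the
background, which a regression test pins down. dN/dS of 0 is retained.
Genes annotated to several classes contribute to each. Proportions are
displayed to one decimal percent (raw fractions kept in machine output);
the essential-among-TRGs fraction is only reported for classes with at
least 20 TRGs.

## The synthetic world

`trgkit.simulate.generate_world` emits every input format the pipeline
consumes, with ground truth in `truth.json`. Defaults are the study
conditions: 2000 genes, 15% taxonomically restricted (typical eukaryotic
genomes run 10–20%), 17% essential overall, 3% of TRGs essential —
echoing the real yeast/worm catalogs, which makes essential TRGs rare
(~9 genes at the default size) exactly as they are in reality.

* **Homology hits.** TRGs receive strong in-lineage hits only; shared
  genes receive strong hits across the out-lineage genomes with E-values
  decaying with phylogenetic rank; 25% of TRGs carry one deliberately
  weak out-lineage hit (E ≈ 10⁻³–10⁻⁵, coverage 0.10–0.25) that fails
  both strict cutoffs but passes a 5%-length/10⁻² relaxed scan, making
  the relaxed-scan fractions exactly predictable. Boundary-straddling
  hits are never emitted, so classification recovers truth exactly. A
  small fraction of shared genes (2%) have no out-lineage homology but
  carry a domain, exercising the domain-exclusion path.
* **Expression** follows a latent-factor model: each of 20 pathways is a
  factor; pathway members load 1 on their factor; essential genes
  additionally load `coexpr_loading` (default 1.0) on each of 3
  "essential pathway" factors; unit Gaussian noise. With loading L, the
  expected correlation between an essential TRG and an essential-pathway
  member is L/√(2(3L²+1)) ≈ 0.35 at L = 1, an effect a few noise
  standard deviations wide after averaging 4 datasets of 20 samples —
  strong enough that recovery is expected, weak enough that the null
  world is clearly distinct.
* **Genomic context.** Essential TRGs sit in high-expression
  neighborhoods (+1.5 log-units to genes within 3 positions) and in
  active chromatin (+1.0 signal units to H3K79-like track bins within
  the gene ± 5 kb; the H3K27-like track carries no planted effect, so
  only the activation mark should test significant). Essential genes as
  a class get +0.5 log-units of own expression.
* **Network.** Eight planted blocks of 40 nodes (p_in = 0.30,
  p_out = 0.01); one block holds TRGs at 3× the global fraction, the
  rest at baseline, with per-block TRG counts fixed (not sampled) so the
  single-enriched-cluster outcome is a property of MCL and the
  enrichment test, not of sampling luck. Essential nodes' edge
  probabilities are multiplied by `degree_bias_essential` (default 2,
  applied as max of endpoint biases) so their expected degree doubles
  while the in/out density ratio that MCL sees is preserved.
* **Protein features and rates.** Ordered fractions are Beta-distributed
  per class (essential TRPs mean 0.50 vs shared essentials 0.85);
  coiled-coil presence is Bernoulli per class (0.85 for essential TRPs
  vs 0.15 for nonessential — with only ~9 essential TRPs a smaller
  contrast would be undetectable at α = 0.01, so the planted effect is
  sized for the class imbalance the fractions impose). dN/dS is Gamma
  (shape 2) per functional class with the scale set from the target
  median; the amino-acid-biosynthesis and chromosome-segregation classes
  are sized 200/231 genes with 7/36 TRGs and medians 0.057/0.113,
  mirroring the real catalog's extremes.
* `WorldConfig.null()` zeroes every planted effect for calibration runs.

**What the generator does not emulate:** real expression is not Gaussian
or factor-structured, real PPI networks are scale-free rather than
blocky, homology E-values are not independent across genomes, and there
is no sequence level at all (disorder and coiled-coil are table inputs by
design). Passing the planted-signal suite therefore shows the pipeline
recovers effects of realistic size and direction through the real file
formats and statistics — not that any real genome would give the same
numbers. Dataset-level numbers from real catalogs (TRG counts, the 0.87
cross-validated AUC) depend on database snapshots and are deliberately
not targets of the synthetic runs.

## Problem sizes and determinism

The test suite runs the full pipeline over a 20-seed grid at the default
2000-gene world for the planted-signal and null-calibration checks, and
uses a 1200-gene world for the shared integration fixtures — sizes at
which every stage's expected effect is computable in advance and a full
grid completes in minutes on one CPU. All randomness flows from explicit
seeds: a config seed fixes every emitted byte of a world, and the CV seed
fixes folds and hence the entire report.

## Known limitations

* The Wilcoxon exact branch is O(C(n₁+n₂, n₁)) and is capped at total
  size 12; no network-flow exact algorithm for larger tied samples.
* The λ-max CV AUC is an optimistic estimate of generalization (no
  nested CV); it mirrors the analysis it implements rather than best
  practice for unbiased error estimation.
* MCL is dense-matrix; fine for the 10²–10³-node networks here, not for
  full interactomes beyond ~10⁴ nodes.
* `class_rate_analysis` treats multi-class genes as independent
  observations in each class's t-test, as the annotation sources do.
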