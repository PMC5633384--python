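# trgkit

A toolkit for studying **taxonomically restricted genes (TRGs)** — genes
with no detectable homology outside a narrow set of closely related
species — and in particular for asking what distinguishes the small
minority of TRGs that are *essential* from the nonessential majority.
Although TRGs encode novel proteins, essential TRGs in model eukaryotes
(budding yeast, nematodes) resemble deeply conserved essential genes in
several measurable ways: coexpression with core cellular pathways,
genomic neighborhood expression and chromatin state, number of
protein–protein interactions, protein disorder and coiled-coil content.
`trgkit` implements that whole analysis as a tested, reusable pipeline,
plus a synthetic-data generator with planted effects so that every stage
can be exercised end to end without any external download.

It is aimed at comparative genomicists and anyone benchmarking
phylostratigraphy-adjacent analyses on controlled synthetic inputs.

## The methods at the core

* **TRG classification.** A gene is taxonomically restricted iff it has no
  BLASTP hit with E-value < 10⁻⁶ covering > 30% of the query protein
  length to any taxon outside the focal lineage, and encodes no annotated
  protein domain. Genes failing only the domain rule are labelled shared
  with an exclusion flag. Classes are the cross of conservation and
  essentiality: TRG-E, TRG-NE, Shared-E, Shared-NE.
* **Coexpression features.** For a TRG *t* and gene *g*, Pearson r is
  computed per expression dataset, Fisher-transformed
  (z = ½ ln((1+r)/(1−r))), averaged across datasets, then averaged over
  the member genes of each pathway to give one feature per (TRG, pathway).
* **Essentiality classifier.** Elastic-net logistic regression
  (α = 0.5), minimizing
  (1/n) Σᵢ log(1 + e^(−ỹᵢ(β₀+xᵢβ))) + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)
  by cyclic coordinate descent on an IRLS majorization, scored by pooled
  out-of-fold ROC AUC over a 50-point λ path in stratified 5-fold CV.
* **Network analysis.** Markov Clustering (inflation 1.5) of the PPI
  graph; hypergeometric upper-tail enrichment of TRGs in every cluster
  with > 30 members, Bonferroni-corrected; Wilcoxon degree comparisons
  restricted to genes with ≥ 1 interaction.
* **Group statistics.** Wilcoxon rank-sum (exact by enumeration for
  n₁+n₂ ≤ 12, tie-corrected normal approximation otherwise), two-sample
  KS, χ² on 2×2 tables, Welch t, Bonferroni correction, rank-based ROC
  AUC — each validated against exact-arithmetic oracles in the test
  suite.

## Worked example

Generate a synthetic world with planted effects and run the full pipeline:

```bash
trg simulate --n-genes 2000 --seed 1 --out world/
trg run --config run.yaml     # or use the Python API below
```

```python
from trgkit.pipeline import RunConfig, run_all
report = run_all(RunConfig.from_world("world/", seed=1))
print(report["stages"]["classify"]["class_counts"])
print(report["stages"]["classifier"]["cv_auc"])
print(report["stages"]["network"]["n_enriched_clusters"])
```

Output for seed 1:

```
{'TRG-E': 9, 'TRG-NE': 291, 'Shared-E': 331, 'Shared-NE': 1369}
1.0
1
```

Read: of 2000 genes, 300 are taxonomically restricted and 9 of those are
essential; the coexpression features separate essential from nonessential
TRGs perfectly in cross-validation at this planted signal strength; and
exactly one MCL cluster of the interaction network is significantly
enriched for TRGs after Bonferroni correction — the planted TRG-rich
block. The per-stage TSVs (classes, features, cluster enrichment, class
dN/dS report, …) land in `world/out/`.

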