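# ecmatlas

Quantitative analytics for **regional extracellular-matrix (ECM)
specialization in the mouse hair follicle**. During the resting (telogen)
phase, the follicle's basement membrane (BM) and interstitial matrix differ
zone by zone — from the interfollicular epidermis down to the interface
between the hair germ (HG) and the dermal papilla (DP) — and those
differences are driven by which cell population expresses which ECM gene.
`ecmatlas` implements the analysis workflow for mapping that specialization
from sorted-population RNA-seq and regional immunofluorescence:

* **Matrisome catalogue** — a 281-gene ECM annotation partitioned into 67
  basement-membrane and 214 interstitial genes, gating every gene-set
  analysis (`ecmatlas.matrisome`).
* **Expression core** — median-of-ratios size normalization, `log2(x+1)`
  transform, per-gene z-scores (`ecmatlas.expression`).
* **Differential expression** — negative-binomial Wald (two-group) and
  likelihood-ratio (multi-group) tests with method-of-moments dispersion,
  Benjamini–Hochberg adjustment, and the epithelial/dermal **origin call**:
  a gene is epithelial- or dermal-enriched when `padj < 0.05` and fold
  change `> 4` between basal epidermis and pan-dermal fibroblasts
  (`ecmatlas.diffexp`).
* **Correlation profiles** — sample-pairwise Spearman matrices on five gene
  panels (all / matrisome / non-matrisome / BM / interstitial) with
  mean ± SD summaries per population pair (`ecmatlas.correlation`).
* **Region programs** — "epi-groups": significant ECM genes
  (`padj < 0.001` across the five epithelial populations) are clustered by
  complete linkage and cut into K = 10 groups; each group's
  relatively-high-expression regions come from an exact two-means split of
  the per-region mean z-scores (`ecmatlas.programs`).
* **GSEA** — weighted running-sum enrichment on a DP vs pan-DF
  signal-to-noise ranking with gene-set permutation; significance means
  FDR q < 0.25 and nominal p < 0.05 (`ecmatlas.gsea`).
* **Deposition atlas** — six-zone protein quantification (background
  subtraction, percent-of-max normalization, Friedman + Wilcoxon/Bonferroni
  region tests), **mRNA–protein concordance** (consistent iff shared peak
  zone and Pearson r > 0.5), and morphometry helpers
  (`ecmatlas.deposition`).
* **Synthetic data** — a seeded generator that emulates the study design
  with planted programs, planted discordant proteins, and labeled images,
  used for every validation (`ecmatlas.simulate`).

## Worked example

```python
from ecmatlas import expression as expr, diffexp, programs as prog, matrisome
from ecmatlas.simulate import SimulationConfig, simulate_counts

catalogue = matrisome.load_default_catalogue()
cm, truth = simulate_counts(SimulationConfig(seed=11), catalogue)

factors = expr.compute_size_factors(cm)
nm = expr.normalize_counts(cm, factors)
z = expr.zscore_genes(expr.log_transform(nm))

lrt = diffexp.lrt_multigroup(cm, factors, list(expr.EPITHELIAL_POPULATIONS))
selected = prog.select_de_ecm_genes(lrt, catalogue, alpha=0.001)
groups = prog.build_epi_groups(z, selected, k=10)
print(len(selected), "significant ECM genes in", len(groups), "epi-groups")
print(prog.recovery_score(groups, truth.program_assignment, truth.program_regions))
```

prints

```
200 significant ECM genes in 10 epi-groups
{'ari': 1.0, 'region_label_accuracy': 1.0}
```

i.e. all 200 planted region-specific ECM genes reach `padj < 0.001`, the
ten recovered epi-groups match the planted gene partition exactly (adjusted
Rand index 1.0), and every group's high-expression regions equal the
planted target populations.

The same pipeline runs from the shell:

```sh
ecmatlas simulate --seed 11 --out bundle/
ecmatlas run-all --config cfg.yaml      # normalize → DE → epi-groups → GSEA → concordance
```

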