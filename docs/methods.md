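# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that tests pin down.

## The matrisome catalogue

All gene-set analyses are gated by a catalogue of 281 mouse ECM genes
partitioned into 67 basement-membrane (BM) and 214 interstitial genes.
Symbols are matched case-insensitively (count tables are inconsistent about
capitalization of mouse symbols) with the catalogue spelling canonical.
The packaged list (`data/matrisome_mouse.tsv`) transcribes
literature-standard mouse matrisome symbols — laminins, collagen IV/VI/VII/
XV/XVII/XVIII, nidogens, perlecan/agrin, Fras/Frem, nephronectin and
netrins on the BM side; fibrillar collagens, fibronectin, tenascins,
fibrillins, SLRPs and other proteoglycans, matricellular glycoproteins,
IGFBPs, CCNs and spondins on the interstitial side. Rows flagged
`placeholder` in the provenance column are synthetic padding that keeps the
281/67/214 totals exact for testing; any analysis of real data should
replace them with the full curated list. Placeholders never affect
synthetic-data results because the generator draws its gene universe from
the catalogue itself.

## Normalization

Size factors use the median-of-ratios estimator: the per-gene reference is
the geometric mean across samples over genes positive everywhere, and a
sample's factor is the median of its count/reference ratios. When no gene
is positive in all samples the default is to fail loudly; an explicit
`allow_pseudo_reference=True` switches to positive-entry geometric means,
so sparse-input problems surface rather than silently changing the
estimator. Downstream values are `log2(normalized + 1)` — a variance-
stabilizing stand-in for a regularized log transform, adequate here because
clustering and labeling are validated on synthetic data generated under the
same model — and per-gene z-scores with the population (divide-by-n) SD;
constant rows map to zero with a warning. "Expressed" defaults to
normalized count ≥ 1 in ≥ 1 sample and is configurable.

## Negative-binomial differential expression

The count model is NB with Var = μ + αμ². Per-gene dispersion is a
method-of-moments estimate on size-normalized counts,
α̂ = max(0, (s² − m)/m²) averaged over groups (all-zero genes get α = 0).

**Two-group Wald.** The moderated log2 fold change is
log2((m_A + 1)/(m_B + 1)); its standard error comes from Var(m̄_g) =
(μ + αμ²)/n_g propagated by the delta method. The statistic is referenced
against **Student t with n_A + n_B − 2 df**, not the normal limit: with
three replicates per group, the plug-in dispersion is noisy enough that
normal tails give ~13–14% false positives at the nominal 5% level, while
the t reference restores ~4.5–5.5% (Monte-Carlo at μ = 100, α = 0.1,
n = 3/3). The pseudocount-1 moderation avoids division by zero; the
fold-change arm of the origin call is a strict inequality (FC = 4.0 exactly
does not qualify).

**Multi-group LRT.** Group means are fitted in closed form as means of
size-normalized counts; the likelihood is evaluated on raw counts with
per-sample means scaled by the size factors and α held fixed. For the same
small-sample reason, the scaled statistic LRT/(k − 1) is referenced against
**F(k − 1, N − k)** instead of χ²(k − 1) (~4.5–5.3% measured type-I error
versus ~13% for χ²). A consequence of the heavier F tails at 6 residual df
is that p-values for very strong effects bottom out more slowly than the
χ² limit would suggest.

**Multiple testing** is Benjamini–Hochberg step-up within the gene family
given to the test (all genes by default; restricting the input restricts
the family).

**Origin call.** A gene is epithelial-enriched iff padj < 0.05 and the
moderated fold change strictly exceeds 4 toward basal epithelium;
dermal-enriched symmetrically; otherwise shared. The basal fraction
(Basal share of summed normalized counts over Basal + pan-DF) is attached.

## Correlation profiles

Spearman rho between sample pairs uses average ranks for ties and is
computed on the gene subset only (no leakage from excluded genes, asserted
by test). A zero-rank-variance sample yields NaN with a warning rather
than a fabricated 0. Inputs default to the log2 stage. Group summaries
report mean and sample SD (n − 1) over all cross-replicate pairs,
excluding self-pairs; within-group summaries use the C(n, 2) distinct
pairs. The five-panel analysis (all / matrisome / non-matrisome / BM /
interstitial) shares one sample ordering so panels are comparable.

## Epi-group discovery

Genes with multi-group padj < 0.001 that are in the catalogue are
clustered by complete-linkage agglomeration and the dendrogram is cut into
exactly K = 10 clusters. The gene-axis distance defaults to **Euclidean on
the epithelial-sample z-scores**: planted-truth experiments showed that
programs spanning overlapping region sets (e.g. {UB} vs {UB, MB}) have
strongly rank-correlated profiles that 1 − Spearman distance cannot
separate (ARI 0.6–0.85), while Euclidean distance recovers the planted
partition exactly (ARI = 1.0 across seeds). `metric="spearman"` remains
available to mirror the sample-axis clustering convention.

Region labeling replaces k-means (k = 2) on the five per-region mean
z-scores with the **exact optimal two-partition**: on one dimension the
k-means optimum is always a contiguous split of the sorted values, so all
four splits are enumerated and the minimal within-cluster sum of squares
wins. This is the same optimum k-means converges to, without seed
sensitivity. WCSS ties go to the partition with the smaller high cluster
(the more region-specific call); replicates are averaged before splitting.
Because a two-partition always has a non-empty low side, a group can never
be labeled "high everywhere"; all-equal region means raise an error.

## GSEA

Genes are ranked by signal-to-noise (m_A − m_B)/(s_A + s_B) with each SD
floored at 0.2·|mean| (0.2 when the mean is zero); ties break
lexicographically so the order is total. The enrichment score is the
signed extremum of the running sum (hits add normalized |metric|^p,
p = 1 by default, p = 0 exposed for closed-form tests; misses subtract
1/(N − |S|)). Significance uses **gene-set permutation** — with three
replicates per phenotype only ten label splits exist, so phenotype
permutation is unusable — with NES = ES / mean(|null ES| same sign),
nominal p the same-sign null tail, and FDR q the standard ratio of pooled
null-NES to observed-NES tail fractions clipped to 1. A set is significant
when FDR q < 0.25 and nominal p < 0.05.

## Deposition atlas and concordance

Zone intensities are means over labeled mask pixels minus the mean of the
paired adjoining-epithelium background region, clipped at zero (negative
deposition is not meaningful). Relative values are percent-of-max — the
brightest zone reads exactly 100 (the division happens before the ×100 so
the peak is exact in floating point). Region enrichment across a protein
panel uses the Friedman test (proteins as blocks, six zones as
treatments); pairwise two-sided Wilcoxon tests with Bonferroni correction
(factor = number of comparisons performed) run only when Friedman
p < 0.05. Wilcoxon uses the exact distribution for small samples and drops
zero differences.

Concordance aligns the five-population mRNA profile onto the six-zone axis
as Basal→IFE, LI→LI, UB→UB, MB→MB, and HG→{LHG, interface} (one hair-germ
expression measurement stands for both hair-germ zones; peak matching
accepts either). The verdict is consistent iff the peak-zone sets
intersect AND Pearson r on the aligned vectors strictly exceeds 0.5 —
r = 0.5 exactly is discrepant, peak ties are compared as sets, and
zero-variance profiles are discrepant with a flag. Morphometry operations
(hemidesmosome count per traced perimeter µm, voxel-count × voxel-volume
3D object volumes, pigmented-pixel fractions with dark-is-pigmented
polarity by default) are direct arithmetic with input validation.

## Synthetic data

The generator emulates the study design: seven populations (Basal, LI, UB,
MB, HG, DP, pan-DF) × 3 replicates; 1000 genes whose baselines are drawn
log-uniformly over [20, 2000] (spanning realistic sequencing depth);
library-size factors log-uniform over [0.7, 1.4]; NB counts with α = 0.05
and Var = μ + αμ² (the same parameterization the tests assume, so recovery
questions are well-posed); ten planted programs of 20 matrisome genes each
with log2 effect 3, covering ten distinct epithelial region patterns
(five singles, four adjacent pairs, one triple). Protein profiles are
positive affine transforms of the population-mean mRNA profile mapped to
zones, plus Gaussian noise with SD = 0.1 × the mean signal by default; a
configurable fraction is made discordant by peak-shifting (the protein
peak is forced outside the mRNA peak set) or decorrelation (zone values
permuted until r < 0.5). Synthetic images place six uniform zone strips
with paired background strips below them. All randomness flows through
one seeded generator; identical seeds give byte-identical bundles.

What the generator does **not** emulate: gene–gene correlation structure,
GC/length biases, sample outliers, batch effects, count overdispersion
heterogeneity across genes, partial-volume and segmentation errors in
images, or antibody-specific staining backgrounds. Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to every artifact of real data.

A named preset (`dp_hg_shared_config`) plants an interstitial program
shared by HG and DP to reproduce the qualitative correlation contrast
(DP more similar to HG than to pan-DF on interstitial genes); tests assert
the direction, not the magnitude, of that contrast.

## Problem sizes

Validation uses 1000-gene simulations with 21 samples, 2000-gene null
calibrations, and 100–1000 permutations for GSEA — sizes at which every
Monte-Carlo quantity reported here is stable to well within its acceptance
band across seeds.

## Known limitations

* The log2(x+1) transform under-stabilizes variance for very low counts
  compared with a shrinkage-based regularized log; on real data the
  expressed-gene filter should be tightened accordingly.
* Dispersion is per-gene method-of-moments without shrinkage across genes;
  power at n = 3 is correspondingly conservative.
* The FDR computation for GSEA pools normalized null scores in the
  simplified standard way; with a single tested set it reduces to a
  null-tail fraction.
* The catalogue's placeholder rows mean division-level counts are exact
  but membership is not a substitute for the curated supplementary list
  when analyzing real data.
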