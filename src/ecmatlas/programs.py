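"""Region-specific ECM expression programs (epi-groups).

Significant matrisome genes (multi-group adjusted p < 0.001 across the five
epithelial populations) are hierarchically clustered — complete linkage on
1 − Spearman rho between gene z-score profiles — and the dendrogram is cut
into K groups (K = 10 in the study design). Each group is then labeled with
the epithelial regions where it is "relatively highly expressed": the five
per-region mean z-scores are split into a high and a low group by an optimal
two-means partition. Because the inputs are five scalars, the k-means
optimum is found exactly by enumerating the contiguous splits of the sorted
values, which removes any dependence on initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .expression import EPITHELIAL_POPULATIONS, NormalizedMatrix, STAGE_ZSCORE
from .matrisome import MatrisomeCatalogue


@dataclass
class EpiGroup:
    """One gene program: its members and the regions where it runs high."""

    id: int
    genes: tuple[str, ...]
    high_regions: tuple[str, ...]
    region_means: dict[str, float]

    @property
    def pattern_code(self) -> str:
        return "+".join(sorted(self.high_regions))


def select_de_ecm_genes(
    de: pd.DataFrame, catalogue: MatrisomeCatalogue, alpha: float = 0.001
) -> list[str]:
    """Matrisome genes with multi-group adjusted p below ``alpha``."""
    significant = de.index[de["padj"] < alpha]
    selected = [g for g in significant if g in catalogue]
    if not selected:
        raise ValueError(
            f"no matrisome gene reached padj < {alpha}; consider a larger alpha"
        )
    return selected


def _gene_spearman_distance(z: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(z, axis=1)
    sd = ranks.std(axis=1)
    # constant profiles carry no ranking information; treat as maximally distant
    safe = np.where(sd == 0, 1.0, sd)
    centered = (ranks - ranks.mean(axis=1, keepdims=True)) / safe[:, None]
    rho = centered @ centered.T / z.shape[1]
    rho[sd == 0, :] = 0.0
    rho[:, sd == 0] = 0.0
    np.fill_diagonal(rho, 1.0)
    return 1.0 - np.clip(rho, -1.0, 1.0)


def cluster_genes(
    z: NormalizedMatrix,
    genes: list[str],
    k: int,
    metric: str = "euclidean",
    populations: tuple[str, ...] | None = None,
) -> dict[str, int]:
    """Cut a complete-linkage dendrogram of gene profiles into exactly ``k`` clusters.

    Profiles are the z-scored values over the samples of ``populations``
    (all samples when None). Euclidean distance is the default — gene
    programs differing only in which regions they span have highly
    rank-correlated profiles, which Spearman distance cannot separate —
    but ``metric="spearman"`` (1 − rho) mirrors the sample-axis clustering
    convention. Returns gene → cluster id (1..k).
    """
    if z.stage != STAGE_ZSCORE:
        raise ValueError("gene clustering expects z-scored values")
    if len(genes) < k:
        raise ValueError(f"cannot cut {len(genes)} genes into {k} clusters")
    sub = z.values.loc[genes].to_numpy(dtype=float)
    if populations is not None:
        mask = np.isin(z.populations(), populations)
        if not mask.any():
            raise ValueError("no samples in the requested populations")
        sub = sub[:, mask]
    if metric == "spearman":
        dist = _gene_spearman_distance(sub)
    elif metric == "euclidean":
        diff = sub[:, None, :] - sub[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(genes, (int(v) for v in labels)))


def two_means_split(values: dict[str, float]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Exact optimal 2-partition of named scalars by within-cluster sum of squares.

    Equivalent to converged k-means with k = 2 on one dimension: the optimum
    is always a threshold split of the sorted values, so all n−1 contiguous
    splits are enumerated. Ties in WCSS go to the partition with the smaller
    high cluster (the more region-specific call). Returns (high, low) keys.
    """
    items = sorted(values.items(), key=lambda kv: (kv[1], kv[0]))
    names = [k for k, _ in items]
    x = np.array([v for _, v in items], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two regions to split")
    if np.ptp(x) == 0:
        raise ValueError("no region specificity: all region means are equal")
    best: tuple[float, int] | None = None
    for cut in range(1, len(x)):  # low = x[:cut], high = x[cut:]
        low, high = x[:cut], x[cut:]
        wcss = ((low - low.mean()) ** 2).sum() + ((high - high.mean()) ** 2).sum()
        # prefer larger cut (smaller high cluster) on ties
        if best is None or wcss < best[0] - 1e-12 or (
            abs(wcss - best[0]) <= 1e-12 and cut > best[1]
        ):
            best = (wcss, cut)
    cut = best[1]
    return tuple(names[cut:]), tuple(names[:cut])


def label_high_regions(
    z: NormalizedMatrix, genes: list[str],
    populations: tuple[str, ...] = EPITHELIAL_POPULATIONS,
) -> tuple[tuple[str, ...], dict[str, float]]:
    """Regions where a gene cluster is relatively highly expressed.

    Region scores are replicate-averaged mean z-scores of the cluster's genes
    per population; the high/low call is the exact two-means split.
    """
    means = z.population_means(populations).loc[genes].mean(axis=0)
    region_means = {pop: float(means[pop]) for pop in populations}
    high, _ = two_means_split(region_means)
    return high, region_means


def build_epi_groups(
    z: NormalizedMatrix,
    genes: list[str],
    k: int = 10,
    populations: tuple[str, ...] = EPITHELIAL_POPULATIONS,
    metric: str = "euclidean",
) -> list[EpiGroup]:
    """Full program discovery: cluster genes, then label each cluster's regions."""
    assignment = cluster_genes(z, genes, k, metric=metric, populations=populations)
    groups = []
    for gid in sorted(set(assignment.values())):
        members = tuple(g for g in genes if assignment[g] == gid)
        high, region_means = label_high_regions(z, list(members), populations)
        groups.append(
            EpiGroup(id=gid, genes=members, high_regions=high, region_means=region_means)
        )
    return groups


def recovery_score(
    epi_groups: list[EpiGroup],
    true_assignment: dict[str, int],
    true_regions: dict[int, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """Compare discovered programs against planted truth.

    Returns the adjusted Rand index between the gene partitions and, when
    planted regions are given, the fraction of discovered groups whose
    high-region set matches the planted region set of their majority truth
    program exactly.
    """
    genes = [g for grp in epi_groups for g in grp.genes if g in true_assignment]
    pred = []
    truth = []
    for grp in epi_groups:
        for g in grp.genes:
            if g in true_assignment:
                pred.append(grp.id)
                truth.append(true_assignment[g])
    ari = float(adjusted_rand_score(truth, pred)) if genes else float("nan")
    out = {"ari": ari}
    if true_regions is not None:
        correct = 0
        scored = 0
        for grp in epi_groups:
            member_truth = [true_assignment[g] for g in grp.genes if g in true_assignment]
            if not member_truth:
                continue
            majority = max(set(member_truth), key=member_truth.count)
            scored += 1
            if set(grp.high_regions) == set(true_regions[majority]):
                correct += 1
        out["region_label_accuracy"] = correct / scored if scored else float("nan")
    return out


def epi_groups_table(groups: list[EpiGroup]) -> pd.DataFrame:
    rows = [
        {"gene": gene, "group_id": grp.id, "pattern_code": grp.pattern_code}
        for grp in groups
        for gene in grp.genes
    ]
    return pd.DataFrame(rows)
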