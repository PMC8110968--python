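"""Weighted running-sum gene-set enrichment with permutation significance.

Genes are ranked by the signal-to-noise ratio between two populations (here
DP vs pan-DF); a gene set's enrichment score (ES) is the signed extremum of
a running sum that rises by the normalized |metric|^p at set members and
falls by 1/(N − |set|) elsewhere. Significance comes from gene-set
permutation: random same-size sets define the null ES distribution, the
normalized score NES divides ES by the mean |null ES| of the same sign, and
a set is called significant when FDR q < 0.25 and nominal p < 0.05.

Gene-set permutation (rather than phenotype permutation) is the standard
fallback when each phenotype has only three replicates — ten distinct label
splits cannot support a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix


@dataclass
class RankedList:
    """Genes in descending metric order (ties broken by symbol)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric must align")
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least two genes")
        self.metric = np.asarray(self.metric, dtype=float)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_genes: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = (self.fdr_q < 0.25) and (self.nominal_p < 0.05)


def rank_by_signal_to_noise(
    nm: NormalizedMatrix, group_a: str, group_b: str
) -> RankedList:
    """Signal-to-noise metric (mean_A − mean_B)/(sd_A + sd_B), descending.

    Per-group SDs (n−1 denominator) are floored at 0.2·|group mean| (0.2 when
    the mean is zero) so low-variance genes do not dominate. Ties are broken
    by gene symbol so the ordering is total and reproducible.
    """
    pops = nm.populations()
    out_sd = []
    out_mean = []
    for label in (group_a, group_b):
        mask = pops == label
        if mask.sum() < 2:
            raise ValueError(f"group {label!r} needs >=2 replicates for signal-to-noise")
        x = nm.values.to_numpy(dtype=float)[:, mask]
        mean = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        floor = 0.2 * np.abs(mean)
        floor = np.where(floor == 0, 0.2, floor)
        out_mean.append(mean)
        out_sd.append(np.maximum(sd, floor))
    metric = (out_mean[0] - out_mean[1]) / (out_sd[0] + out_sd[1])
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], nm.values.index[i]))
    genes = [nm.values.index[i] for i in order]
    return RankedList(genes=genes, metric=metric[order])


def enrichment_score(
    rl: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running-sum profile for one gene set.

    Hits increment by |metric|^weight normalized over the set's hits; misses
    decrement by 1/(N − n_hits). The ES is the running-sum value of largest
    absolute magnitude (signed). Raises if the set is disjoint from the list.
    """
    positions = rl.index
    hit_idx = sorted(positions[g] for g in gene_set if g in positions)
    if not hit_idx:
        raise ValueError("gene set shares no genes with the ranked list")
    n = len(rl.genes)
    n_hits = len(hit_idx)
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list; no misses to score")
    is_hit = np.zeros(n, dtype=bool)
    is_hit[hit_idx] = True
    weights = np.abs(rl.metric) ** weight
    hit_weights = np.where(is_hit, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:  # all hit metrics are zero; fall back to unweighted steps
        hit_weights = is_hit.astype(float)
        total = float(n_hits)
    steps = np.where(is_hit, hit_weights / total, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    return float(running[extremum]), running


def _null_es(
    rl: RankedList, set_size: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(rl.genes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        null[i], _ = enrichment_score(
            rl, [rl.genes[j] for j in idx], weight=weight
        )
    return null


def permutation_significance(
    rl: RankedList,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Gene-set permutation significance for one or more sets.

    NES = ES / mean(|null ES| of the same sign); nominal p is the same-sign
    null fraction at least as extreme as the observed ES; FDR q is the
    standard ratio of null-NES to observed-NES tail fractions, clipped to 1.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    observed = {}
    nulls = {}
    for name, members in gene_sets.items():
        es, _ = enrichment_score(rl, members, weight=weight)
        size = sum(1 for g in members if g in rl.index)
        observed[name] = (es, size)
        nulls[name] = _null_es(rl, size, n_perm, weight, rng)

    def _nes(es: float, null: np.ndarray) -> float:
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        return es / denom if denom > 0 else 0.0

    nes_obs = {name: _nes(es, nulls[name]) for name, (es, _) in observed.items()}
    nes_null = {
        name: np.array([_nes(v, nulls[name]) for v in nulls[name]])
        for name in gene_sets
    }
    pooled_null = np.concatenate(list(nes_null.values()))
    all_obs = np.array(list(nes_obs.values()))

    results = []
    for name, (es, size) in observed.items():
        null = nulls[name]
        if es >= 0:
            same = null[null >= 0]
            nominal_p = float((same >= es).mean()) if same.size else 0.0
        else:
            same = null[null < 0]
            nominal_p = float((same <= es).mean()) if same.size else 0.0
        nes = nes_obs[name]
        if nes >= 0:
            null_tail = (pooled_null[pooled_null >= 0] >= nes).mean() if (pooled_null >= 0).any() else 0.0
            obs_tail = (all_obs[all_obs >= 0] >= nes).mean()
        else:
            null_tail = (pooled_null[pooled_null < 0] <= nes).mean() if (pooled_null < 0).any() else 0.0
            obs_tail = (all_obs[all_obs < 0] <= nes).mean()
        fdr_q = float(min(1.0, null_tail / obs_tail)) if obs_tail > 0 else 1.0
        results.append(
            GseaResult(
                set_name=name,
                es=float(es),
                nes=float(nes),
                nominal_p=nominal_p,
                fdr_q=fdr_q,
                n_genes=size,
            )
        )
    return results


def results_table(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "ES": r.es,
                "NES": r.nes,
                "nominal_p": r.nominal_p,
                "FDR_q": r.fdr_q,
                "n_genes": r.n_genes,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name, description, then tab-separated symbols."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *members]) + "\n")
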