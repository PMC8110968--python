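"""Sample-pairwise Spearman correlation on gene subsets, with group summaries.

This is the sample-similarity analysis run separately on all expressed genes,
matrisome genes, non-matrisome genes, and the BM / interstitial divisions:
identical sample orderings across panels so the matrices are directly
comparable, plus mean ± SD summaries over replicate pairs for each
population pair (e.g. the DP–HG vs DP–panDF comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

from .expression import NormalizedMatrix
from .matrisome import BM, INTERSTITIAL, MatrisomeCatalogue

PANEL_TAGS = ("all", "matrisome", "non_matrisome", "BM", "interstitial")


@dataclass
class CorrelationMatrix:
    samples: tuple
    rho: pd.DataFrame  # samples × samples
    gene_set_tag: str

    def __post_init__(self) -> None:
        if not self.rho.index.equals(self.rho.columns):
            raise ValueError("correlation matrix must be square with matching labels")


def spearman_pairwise(nm: NormalizedMatrix, gene_set, tag: str = "custom") -> CorrelationMatrix:
    """Spearman rho between all sample pairs, restricted to ``gene_set`` rows.

    Ties get average ranks. A sample whose restricted vector has zero rank
    variance yields undefined correlations, recorded as NaN with a warning.
    Requires >=3 overlapping genes.
    """
    genes = [g for g in gene_set if g in nm.values.index]
    if len(genes) < 3:
        raise ValueError(
            f"gene set {tag!r}: only {len(genes)} of its genes overlap the matrix; need >=3"
        )
    sub = nm.values.loc[genes].to_numpy(dtype=float)
    ranks = stats.rankdata(sub, axis=0)
    sd = ranks.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = list(nm.values.columns[degenerate])
        warnings.warn(
            f"gene set {tag!r}: zero rank variance in sample(s) {bad}; rho set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, np.where(degenerate, np.nan, 1.0))
    frame = pd.DataFrame(rho, index=nm.values.columns, columns=nm.values.columns)
    return CorrelationMatrix(samples=nm.samples, rho=frame, gene_set_tag=tag)


def summarize_group_pairs(cm: CorrelationMatrix) -> pd.DataFrame:
    """Mean ± SD of rho over replicate pairs for every unordered population pair.

    Self-pairs (a sample with itself) are excluded; within-group summaries use
    the C(n, 2) distinct replicate pairs. SD is the sample SD (n-1 denominator),
    reported as 0 for a single pair.
    """
    populations = [s.population for s in cm.samples]
    ids = list(cm.rho.index)
    by_pop: dict[str, list[str]] = {}
    for pop, sid in zip(populations, ids):
        by_pop.setdefault(pop, []).append(sid)

    rows = []
    for pop_a, pop_b in combinations_with_replacement(sorted(by_pop), 2):
        if pop_a == pop_b:
            pairs = list(combinations(by_pop[pop_a], 2))
        else:
            pairs = [(x, y) for x in by_pop[pop_a] for y in by_pop[pop_b]]
        if not pairs:
            continue
        values = np.array([cm.rho.at[x, y] for x, y in pairs], dtype=float)
        rows.append(
            {
                "group_a": pop_a,
                "group_b": pop_b,
                "mean_rho": float(np.nanmean(values)),
                "sd_rho": float(np.nanstd(values, ddof=1)) if len(values) > 1 else 0.0,
                "n_pairs": len(pairs),
            }
        )
    return pd.DataFrame(rows)


def group_pair_mean(summary: pd.DataFrame, pop_a: str, pop_b: str) -> float:
    """Mean rho for one unordered population pair from a summary table."""
    a, b = sorted([pop_a, pop_b])
    row = summary[(summary.group_a == a) & (summary.group_b == b)]
    if row.empty:
        raise KeyError(f"no summary for population pair ({pop_a}, {pop_b})")
    return float(row.mean_rho.iloc[0])


def run_setwise_panel(
    nm: NormalizedMatrix,
    catalogue: MatrisomeCatalogue,
    expressed: pd.Index | None = None,
) -> dict[str, CorrelationMatrix]:
    """The five-panel correlation analysis over identical sample orderings.

    Panels: all (expressed) genes, matrisome, non-matrisome, BM, interstitial.
    Matrisome and non-matrisome partition the "all" set; BM and interstitial
    partition the matrisome set.
    """
    universe = list(expressed) if expressed is not None else list(nm.values.index)
    matrisome = [g for g in universe if g in catalogue]
    non_matrisome = [g for g in universe if g not in catalogue]
    bm = [g for g in matrisome if catalogue.lookup(g).division == BM]
    inter = [g for g in matrisome if catalogue.lookup(g).division == INTERSTITIAL]
    sets = {
        "all": universe,
        "matrisome": matrisome,
        "non_matrisome": non_matrisome,
        "BM": bm,
        "interstitial": inter,
    }
    return {tag: spearman_pairwise(nm, genes, tag=tag) for tag, genes in sets.items()}


def write_panel(panel: dict[str, CorrelationMatrix], out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for tag, cm in panel.items():
        cm.rho.rename_axis("sample").to_csv(
            out_dir / f"correlation_{tag}.tsv", sep="\t", float_format="%.10g"
        )
        summarize_group_pairs(cm).to_csv(
            out_dir / f"correlation_{tag}_summary.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
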