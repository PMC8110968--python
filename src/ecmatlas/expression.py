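"""Count matrices with population metadata and their normalized derivatives.

Size normalization follows the median-of-ratios estimator: each sample's
factor is the median, over genes positive in every sample, of that sample's
count divided by the gene's geometric-mean reference. Downstream stages use
``log2(size-normalized + pseudocount)`` in place of a regularized log
transform, and per-gene z-scores (population SD) for clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

POPULATIONS = ("Basal", "LI", "UB", "MB", "HG", "DP", "panDF")
EPITHELIAL_POPULATIONS = ("Basal", "LI", "UB", "MB", "HG")

STAGE_SIZE = "size_normalized"
STAGE_LOG2 = "log2"
STAGE_ZSCORE = "zscore"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str
    replicate: int

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"unknown population {self.population!r}; expected one of {POPULATIONS}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")


def _check_unique_pairs(samples: Sequence[SampleMeta]) -> None:
    pairs = [(s.population, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ValueError("(population, replicate) pairs must be unique")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_id values must be unique")


@dataclass
class CountMatrix:
    """Gene × sample non-negative integer counts with sample metadata."""

    counts: pd.DataFrame  # index: gene symbols, columns: sample ids
    samples: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        _check_unique_pairs(self.samples)
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("count columns must match sample metadata order")
        if self.counts.index.has_duplicates:
            raise ValueError("gene symbols must be unique")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])


@dataclass
class NormalizedMatrix:
    """Real-valued gene × sample matrix tagged with its processing stage."""

    values: pd.DataFrame
    samples: tuple[SampleMeta, ...]
    stage: str

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("value columns must match sample metadata order")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])

    def population_means(self, populations: Sequence[str] | None = None) -> pd.DataFrame:
        """Replicate-averaged values per population (genes × populations)."""
        pops = self.populations()
        wanted = list(populations) if populations is not None else list(dict.fromkeys(pops))
        cols = {}
        for pop in wanted:
            mask = pops == pop
            if not mask.any():
                raise KeyError(f"population {pop!r} absent from matrix")
            cols[pop] = self.values.loc[:, mask].mean(axis=1)
        return pd.DataFrame(cols)


def compute_size_factors(cm: CountMatrix, *, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample.

    The per-gene reference is the geometric mean across samples, using genes
    with strictly positive counts in every sample. If no such gene exists the
    default is to raise; ``allow_pseudo_reference=True`` instead computes each
    gene's geometric mean over its positive entries only.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref_rows = counts[all_positive]
        log_ref = np.log(ref_rows).mean(axis=1)
        ratios = np.log(ref_rows) - log_ref[:, None]
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        log_ref = np.nanmean(logs, axis=1)
        usable = np.isfinite(log_ref)
        if not usable.any():
            raise ValueError("no gene with any positive count; cannot normalize")
        ratios = logs[usable] - log_ref[usable, None]
    else:
        raise ValueError(
            "no gene has positive counts in every sample; rerun with "
            "allow_pseudo_reference=True to use positive-entry geometric means"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_factors = np.nanmedian(ratios, axis=0)
    factors = np.exp(log_factors)
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("size-factor estimation produced non-positive factors")
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def normalize_counts(cm: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """Divide each sample column by its size factor."""
    factors = factors.reindex(cm.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    values = cm.counts.astype(float).div(factors, axis=1)
    return NormalizedMatrix(values=values, samples=cm.samples, stage=STAGE_SIZE)


def log_transform(nm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """``log2(value + pseudocount)`` on size-normalized values."""
    if nm.stage != STAGE_SIZE:
        raise ValueError(f"expected stage {STAGE_SIZE!r}, got {nm.stage!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (nm.values.to_numpy() < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return NormalizedMatrix(
        values=np.log2(nm.values + pseudocount), samples=nm.samples, stage=STAGE_LOG2
    )


def zscore_genes(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene z-scores (population SD). Constant rows map to zero with a warning."""
    if nm.stage != STAGE_LOG2:
        raise ValueError(f"expected stage {STAGE_LOG2!r}, got {nm.stage!r}")
    values = nm.values.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) mapped to all-zero z-scores",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    return NormalizedMatrix(
        values=pd.DataFrame(z, index=nm.values.index, columns=nm.values.columns),
        samples=nm.samples,
        stage=STAGE_ZSCORE,
    )


def filter_expressed(nm: NormalizedMatrix, min_value: float = 1.0,
                     min_samples: int = 1) -> pd.Index:
    """Genes with size-normalized value >= ``min_value`` in >= ``min_samples`` samples."""
    if nm.stage != STAGE_SIZE:
        raise ValueError(f"expected stage {STAGE_SIZE!r}, got {nm.stage!r}")
    keep = (nm.values >= min_value).sum(axis=1) >= min_samples
    return nm.values.index[keep]


# ---------------------------------------------------------------------------
# TSV I/O


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column ``gene``) and its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "population", "replicate"}
    if missing := required - set(sheet.columns):
        raise ValueError(f"sample sheet missing column(s) {sorted(missing)}")
    samples = tuple(
        SampleMeta(row.sample_id, row.population, int(row.replicate))
        for row in sheet.itertuples()
    )
    counts = counts.loc[:, [s.sample_id for s in samples]]
    return CountMatrix(counts=counts.round().astype(np.int64), samples=samples)


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    with Path(samples_path).open("w", encoding="utf-8") as handle:
        handle.write("sample_id\tpopulation\treplicate\n")
        for s in cm.samples:
            handle.write(f"{s.sample_id}\t{s.population}\t{s.replicate}\n")


def subset_populations(cm: CountMatrix, populations: Sequence[str]) -> CountMatrix:
    """Restrict a count matrix to the given populations (order preserved)."""
    keep = [s for s in cm.samples if s.population in set(populations)]
    if not keep:
        raise ValueError(f"no samples in populations {list(populations)}")
    return CountMatrix(
        counts=cm.counts.loc[:, [s.sample_id for s in keep]], samples=tuple(keep)
    )


def stage_values(nm: NormalizedMatrix, stage: str) -> NormalizedMatrix:
    """Advance a size-normalized matrix to the requested stage."""
    if stage == nm.stage:
        return nm
    if nm.stage != STAGE_SIZE:
        raise ValueError("stage promotion starts from a size-normalized matrix")
    if stage == STAGE_LOG2:
        return log_transform(nm)
    if stage == STAGE_ZSCORE:
        return zscore_genes(log_transform(nm))
    raise ValueError(f"unknown stage {stage!r}")
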