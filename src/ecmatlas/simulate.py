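"""Synthetic study generator with planted ground truth.

Emulates the structure of the sorted-population RNA-seq design and the
six-zone protein-deposition measurements so every pipeline stage can be
validated against known truth:

* NB-distributed counts (Var = mu + alpha*mu^2, matching the test model)
  for five epithelial populations, dermal papilla (DP) and pan-dermal
  fibroblasts (pan-DF), three replicates each, with planted
  population-specific gene programs of configurable log2 effect;
* per-gene six-zone protein profiles built as positive affine transforms of
  the population-mean mRNA profile plus Gaussian noise, with a configurable
  fraction of planted discordant genes (peak-shifted or decorrelated);
* labeled synthetic intensity images (six zones plus paired background
  strips) with known per-zone means.

All randomness flows through one seeded generator; a config with the same
seed reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr
from . import matrisome
from .deposition import ZONES, map_mrna_to_zones
from .expression import CountMatrix, SampleMeta

EPITHELIAL = expr.EPITHELIAL_POPULATIONS
ALL_POPULATIONS = expr.POPULATIONS

#: ten distinct epithelial region patterns for the default planted programs
DEFAULT_PROGRAM_REGIONS: tuple[tuple[str, ...], ...] = (
    ("Basal",),
    ("LI",),
    ("UB",),
    ("MB",),
    ("HG",),
    ("Basal", "LI"),
    ("LI", "UB"),
    ("UB", "MB"),
    ("MB", "HG"),
    ("UB", "MB", "HG"),
)


@dataclass
class PlantedProgram:
    """One planted program: which populations it boosts, how many genes, how much."""

    targets: tuple[str, ...]
    n_genes: int = 20
    log2_effect: float = 3.0
    division: str | None = None  # restrict planted genes to BM or interstitial

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        if self.division is not None and self.division not in matrisome.DIVISIONS:
            raise ValueError(f"unknown division {self.division!r}")
        unknown = set(self.targets) - set(ALL_POPULATIONS)
        if unknown:
            raise ValueError(f"unknown target population(s) {sorted(unknown)}")
        if self.n_genes < 1:
            raise ValueError("program needs at least one gene")
        if not np.isfinite(self.log2_effect):
            raise ValueError("log2 effect must be finite")


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults are the study conditions used throughout."""

    seed: int
    n_genes: int = 1000
    n_replicates: int = 3
    programs: tuple[PlantedProgram, ...] = tuple(
        PlantedProgram(targets=regions) for regions in DEFAULT_PROGRAM_REGIONS
    )
    dispersion: float = 0.05
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    protein_noise_sd: float = 0.1  # relative to the mean mRNA zone signal
    discordant_fraction: float = 0.1
    discordance_mode: str = "peak_shift"  # or "decorrelate"
    image_shape: tuple[int, int] = (120, 240)
    image_zone_means: tuple[float, ...] = (40.0, 60.0, 90.0, 150.0, 110.0, 200.0)
    image_background_mean: float = 20.0
    image_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.programs = tuple(self.programs)
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ValueError("need >=1 gene and >=2 replicates")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.discordant_fraction <= 1:
            raise ValueError("discordant fraction must lie in [0, 1]")
        if self.discordance_mode not in ("peak_shift", "decorrelate"):
            raise ValueError(f"unknown discordance mode {self.discordance_mode!r}")
        if len(self.image_zone_means) != len(ZONES):
            raise ValueError(f"need {len(ZONES)} zone means")
        planted = sum(p.n_genes for p in self.programs)
        if planted > self.n_genes:
            raise ValueError("planted programs exceed the gene budget")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the data."""

    program_assignment: dict[str, int] = field(default_factory=dict)  # gene -> program id
    program_regions: dict[int, tuple[str, ...]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    concordance_status: dict[str, str] = field(default_factory=dict)  # concordant|discordant
    zone_means: dict[str, float] = field(default_factory=dict)
    background_mean: float = 0.0


def dp_hg_shared_config(seed: int, n_genes: int = 800) -> SimulationConfig:
    """Preset: an interstitial program shared by the hair germ and the dermal
    papilla, the scenario behind the DP–HG vs DP–panDF correlation contrast."""
    programs = (
        PlantedProgram(targets=("HG", "DP"), n_genes=40, log2_effect=3.0,
                       division=matrisome.INTERSTITIAL),
        PlantedProgram(targets=("Basal", "LI", "UB", "MB"), n_genes=30, log2_effect=2.0),
        PlantedProgram(targets=("panDF",), n_genes=30, log2_effect=2.0,
                       division=matrisome.INTERSTITIAL),
    )
    return SimulationConfig(seed=seed, n_genes=n_genes, programs=programs)


def _gene_names(cfg: SimulationConfig, catalogue: matrisome.MatrisomeCatalogue,
                rng: np.random.Generator) -> tuple[list[str], dict[str, int]]:
    """Gene universe: planted programs use matrisome symbols, the rest is
    catalogue remainder plus background filler."""
    pool = list(catalogue.symbols())
    rng.shuffle(pool)
    names: list[str] = []
    assignment: dict[str, int] = {}
    for pid, program in enumerate(cfg.programs, start=1):
        if program.division is None:
            eligible = pool
        else:
            eligible = [g for g in pool if catalogue.lookup(g).division == program.division]
        if len(eligible) < program.n_genes:
            raise ValueError("catalogue too small for the planted programs")
        members = eligible[-program.n_genes:]
        for g in members:
            assignment[g] = pid
            pool.remove(g)
        names.extend(members)
    names.extend(pool)  # remaining matrisome genes, unplanted
    n_background = cfg.n_genes - len(names)
    if n_background < 0:
        names = names[: cfg.n_genes]
    else:
        names.extend(f"Gene{i:05d}" for i in range(1, n_background + 1))
    return names, assignment


def simulate_counts(
    cfg: SimulationConfig, catalogue: matrisome.MatrisomeCatalogue | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB count matrix with planted population-specific programs.

    count_gs ~ NB(mean = baseline_g * 2^effect * libsize_s, dispersion alpha)
    where the effect applies when the sample's population is in the gene's
    program targets. Deterministic given the config seed.
    """
    if catalogue is None:
        catalogue = matrisome.load_default_catalogue()
    rng = np.random.default_rng(cfg.seed)
    genes, assignment = _gene_names(cfg, catalogue, rng)

    samples = tuple(
        SampleMeta(f"{pop}_{r}", pop, r)
        for pop in ALL_POPULATIONS
        for r in range(1, cfg.n_replicates + 1)
    )
    lo, hi = cfg.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    slo, shi = cfg.libsize_range
    libsize = np.exp(rng.uniform(np.log(slo), np.log(shi), size=len(samples)))

    effects = np.zeros((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        pid = assignment.get(gene)
        if pid is None:
            continue
        targets = set(cfg.programs[pid - 1].targets)
        for si, s in enumerate(samples):
            if s.population in targets:
                effects[gi, si] = cfg.programs[pid - 1].log2_effect

    mu = baselines[:, None] * np.exp2(effects) * libsize[None, :]
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    cm = CountMatrix(
        counts=pd.DataFrame(
            counts.astype(np.int64), index=pd.Index(genes, name="gene"),
            columns=[s.sample_id for s in samples],
        ),
        samples=samples,
    )
    truth = SyntheticTruth(
        program_assignment=assignment,
        program_regions={
            pid: tuple(p.targets) for pid, p in enumerate(cfg.programs, start=1)
        },
        baselines={g: float(b) for g, b in zip(genes, baselines)},
        size_factors={s.sample_id: float(f) for s, f in zip(samples, libsize)},
    )
    return cm, truth


def _shift_peak(profile: np.ndarray, mrna_peaks: set[int], rng: np.random.Generator) -> np.ndarray:
    """Force the protein peak into a zone outside the mRNA peak set."""
    out = profile.copy()
    candidates = [i for i in range(len(profile)) if i not in mrna_peaks]
    target = int(rng.choice(candidates))
    out[target] = profile.max() * 1.5 + 1.0
    for i in mrna_peaks:
        out[i] = profile.min()
    return out


def _decorrelate(profile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute zone values until Pearson r with the original drops below 0.5."""
    for _ in range(200):
        perm = rng.permutation(profile)
        if np.std(perm) == 0:
            break
        if np.corrcoef(profile, perm)[0, 1] < 0.5:
            return perm
    # degenerate profiles: swap extremes as a last resort
    out = profile.copy()
    imax, imin = int(np.argmax(out)), int(np.argmin(out))
    out[imax], out[imin] = out[imin], out[imax]
    return out


def simulate_deposition_profiles(
    cfg: SimulationConfig,
    cm: CountMatrix,
    truth: SyntheticTruth,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Six-zone protein profiles matched to the simulated mRNA.

    Concordant genes get ``protein = a + b * mrna_zone_profile + noise`` with
    a >= 0, b > 0; a planted fraction is made discordant by peak shifting or
    decorrelation. Returns proteins × zones raw intensities; ``truth`` is
    updated with each gene's planted status.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    factors = expr.compute_size_factors(cm)
    nm = expr.normalize_counts(cm, factors)
    pop_means = nm.population_means(EPITHELIAL)
    if genes is None:
        genes = sorted(truth.program_assignment)
    profiles = {}
    n_discordant = int(round(cfg.discordant_fraction * len(genes)))
    discordant = set(rng.choice(len(genes), size=n_discordant, replace=False).tolist())
    for i, gene in enumerate(genes):
        mrna = map_mrna_to_zones(pop_means.loc[gene]).to_numpy()
        a = rng.uniform(0.0, 0.05 * max(mrna.max(), 1.0))
        b = rng.uniform(0.5, 2.0)
        protein = a + b * mrna
        if i in discordant:
            peaks = set(np.flatnonzero(mrna == mrna.max()).tolist())
            if cfg.discordance_mode == "peak_shift":
                protein = _shift_peak(protein, peaks, rng)
            else:
                protein = _decorrelate(protein, rng)
            truth.concordance_status[gene] = "discordant"
        else:
            truth.concordance_status[gene] = "concordant"
        if cfg.protein_noise_sd > 0:
            protein = protein + rng.normal(
                0.0, cfg.protein_noise_sd * protein.mean(), size=len(protein)
            )
        profiles[gene] = np.clip(protein, 0.0, None)
    return pd.DataFrame(profiles, index=list(ZONES)).T


def simulate_labeled_image(
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Synthetic intensity image with six zone strips and paired backgrounds.

    Zones are disjoint vertical strips in the top half; each zone's paired
    background strip sits directly below it in the bottom half. Pixel values
    are the true means plus Gaussian noise.
    """
    h, w = cfg.image_shape
    n = len(ZONES)
    strip = w // n
    if strip < 2 or h < 4:
        raise ValueError("image too small for six zones")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    zone_mask = np.zeros((h, w), dtype=np.int32)
    bg_mask = np.zeros((h, w), dtype=np.int32)
    image = np.full((h, w), cfg.image_background_mean, dtype=float)
    for z in range(n):
        c0, c1 = z * strip, (z + 1) * strip
        zone_slice = (slice(0, h // 2), slice(c0, c1))
        bg_slice = (slice(h // 2, h), slice(c0, c1))
        if (zone_mask[zone_slice] != 0).any() or (bg_mask[bg_slice] != 0).any():
            raise ValueError("zone geometry overlaps")
        zone_mask[zone_slice] = z + 1
        bg_mask[bg_slice] = z + 1
        image[zone_slice] = cfg.image_zone_means[z]
    if cfg.image_noise_sd > 0:
        image = image + rng.normal(0.0, cfg.image_noise_sd, size=image.shape)
    truth = SyntheticTruth(
        zone_means={zone: float(m) for zone, m in zip(ZONES, cfg.image_zone_means)},
        background_mean=float(cfg.image_background_mean),
    )
    return image, zone_mask, bg_mask, truth


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete runnable fixture bundle: counts + sample sheet,
    catalogue, GMT gene sets, deposition measurements, TIFF images, truth JSON.

    Rerunning with the same config produces byte-identical text outputs.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalogue = matrisome.load_default_catalogue()
    cm, truth = simulate_counts(cfg, catalogue)
    profiles = simulate_deposition_profiles(cfg, cm, truth)
    image, zone_mask, bg_mask, image_truth = simulate_labeled_image(cfg)

    paths = {
        "counts": out_dir / "counts.tsv",
        "samples": out_dir / "samples.tsv",
        "catalogue": out_dir / "catalogue.tsv",
        "gene_sets": out_dir / "gene_sets.gmt",
        "deposition": out_dir / "deposition.csv",
        "image": out_dir / "image.tif",
        "zone_mask": out_dir / "zone_mask.tif",
        "background_mask": out_dir / "background_mask.tif",
        "truth": out_dir / "truth.json",
    }
    expr.write_counts(cm, paths["counts"], paths["samples"])
    matrisome.write_catalogue(catalogue, paths["catalogue"])

    from .gsea import write_gmt

    hg_programs = [
        pid for pid, regions in truth.program_regions.items() if "HG" in regions
    ]
    hg_genes = sorted(
        g for g, pid in truth.program_assignment.items() if pid in hg_programs
    )
    sets = {"BM_GENES": sorted(catalogue.symbols(matrisome.BM))}
    if hg_genes:
        sets["HG_ECM_GENES"] = hg_genes
    write_gmt(sets, paths["gene_sets"])

    background_offset = 10.0
    rows = []
    for gene in profiles.index:
        for zone in ZONES:
            rows.append(
                {
                    "protein": gene,
                    "zone": zone,
                    "mean_intensity": float(profiles.at[gene, zone]) + background_offset,
                    "background_intensity": background_offset,
                }
            )
    pd.DataFrame(rows).to_csv(paths["deposition"], index=False, float_format="%.10g")

    tifffile.imwrite(paths["image"], image.astype(np.float32))
    tifffile.imwrite(paths["zone_mask"], zone_mask)
    tifffile.imwrite(paths["background_mask"], bg_mask)

    truth_doc = {
        "config": _config_doc(cfg),
        "program_assignment": truth.program_assignment,
        "program_regions": {str(k): list(v) for k, v in truth.program_regions.items()},
        "concordance_status": truth.concordance_status,
        "image_zone_means": image_truth.zone_means,
        "image_background_mean": image_truth.background_mean,
    }
    paths["truth"].write_text(
        json.dumps(truth_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths


def _config_doc(cfg: SimulationConfig) -> dict:
    doc = asdict(cfg)
    doc["programs"] = [asdict(p) for p in cfg.programs]
    return doc
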