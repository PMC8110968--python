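"""End-to-end orchestration: simulate/load → normalize → DE → programs →
correlation → GSEA → deposition/concordance, with a reproducibility manifest.

Every stage writes plain TSV/JSON with fixed float formatting, so reruns
with an identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import pandas as pd
import yaml

from . import correlation as corr
from . import deposition as depo
from . import diffexp
from . import expression as expr
from . import gsea
from . import matrisome
from . import programs as prog
from . import simulate as sim

log = logging.getLogger("ecmatlas")

_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # fixture bundle; None → simulate
    de_alpha: float = 0.001
    origin_padj: float = 0.05
    origin_fc: float = 4.0
    n_programs: int = 10
    gsea_n_perm: int = 500
    gsea_weight: float = 1.0
    concordance_r: float = 0.5
    expressed_min_value: float = 1.0
    expressed_min_samples: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.de_alpha < 1, "de_alpha must lie in (0, 1)"),
            (0 < self.origin_padj < 1, "origin_padj must lie in (0, 1)"),
            (self.origin_fc > 0, "origin_fc must be positive"),
            (self.n_programs >= 1, "n_programs must be >= 1"),
            (self.gsea_n_perm >= 100, "gsea_n_perm must be >= 100"),
            (0 <= self.concordance_r <= 1, "concordance_r must lie in [0, 1]"),
            (self.expressed_min_samples >= 0, "expressed_min_samples must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(message)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    def digest(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the map of written outputs.

    Raises :class:`StageError` naming the failing stage.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name):
        log.info("stage %s", name)
        return name

    stage = _stage("inputs")
    try:
        if config.input_dir is None:
            bundle_dir = out_dir / "inputs"
            cfg = sim.SimulationConfig(seed=config.seed)
            sim.write_fixture_bundle(cfg, bundle_dir)
        else:
            bundle_dir = Path(config.input_dir)
        cm = expr.read_counts(bundle_dir / "counts.tsv", bundle_dir / "samples.tsv")
        catalogue = matrisome.load_catalogue(bundle_dir / "catalogue.tsv")
        gene_sets = gsea.read_gmt(bundle_dir / "gene_sets.gmt")
        deposition_table = pd.read_csv(bundle_dir / "deposition.csv")

        stage = _stage("normalize")
        factors = expr.compute_size_factors(cm)
        nm = expr.normalize_counts(cm, factors)
        logged = expr.log_transform(nm)
        z = expr.zscore_genes(logged)
        expressed = expr.filter_expressed(
            nm, config.expressed_min_value, config.expressed_min_samples
        )
        factors.to_frame().rename_axis("sample").to_csv(
            out_dir / "size_factors.tsv", sep="\t", float_format=_FLOAT
        )
        outputs["size_factors"] = out_dir / "size_factors.tsv"

        stage = _stage("diffexp")
        wald = diffexp.wald_two_group(nm, "Basal", "panDF")
        origin = diffexp.call_origin(
            wald, nm,
            thresholds=diffexp.OriginThresholds(config.origin_padj, config.origin_fc),
        )
        de_out = wald.join(origin)
        diffexp.write_de_table(de_out, out_dir / "de_basal_vs_pandf.tsv")
        outputs["de_basal_vs_pandf"] = out_dir / "de_basal_vs_pandf.tsv"

        lrt = diffexp.lrt_multigroup(cm, factors, list(expr.EPITHELIAL_POPULATIONS))
        diffexp.write_de_table(lrt, out_dir / "de_epithelial_lrt.tsv")
        outputs["de_epithelial_lrt"] = out_dir / "de_epithelial_lrt.tsv"

        stage = _stage("epi_groups")
        selected = prog.select_de_ecm_genes(lrt, catalogue, alpha=config.de_alpha)
        groups = prog.build_epi_groups(z, selected, k=config.n_programs)
        prog.epi_groups_table(groups).to_csv(
            out_dir / "epi_groups.tsv", sep="\t", index=False
        )
        region_means = {
            str(g.id): {k: round(v, 10) for k, v in g.region_means.items()}
            for g in groups
        }
        (out_dir / "epi_group_region_means.json").write_text(
            json.dumps(region_means, indent=2, sort_keys=True) + "\n"
        )
        outputs["epi_groups"] = out_dir / "epi_groups.tsv"
        outputs["epi_group_region_means"] = out_dir / "epi_group_region_means.json"

        stage = _stage("correlation")
        panel = corr.run_setwise_panel(logged, catalogue, expressed=expressed)
        corr.write_panel(panel, out_dir / "correlation")
        outputs["correlation"] = out_dir / "correlation"

        stage = _stage("gsea")
        ranked = gsea.rank_by_signal_to_noise(nm, "DP", "panDF")
        results = gsea.permutation_significance(
            ranked, gene_sets, n_perm=config.gsea_n_perm,
            weight=config.gsea_weight, seed=config.seed,
        )
        gsea.results_table(results).to_csv(
            out_dir / "gsea.tsv", sep="\t", index=False, float_format=_FLOAT
        )
        outputs["gsea"] = out_dir / "gsea.tsv"

        stage = _stage("deposition")
        profiles = []
        for protein, sub in deposition_table.groupby("protein", sort=True):
            profiles.append(depo.profile_from_measurements(protein, sub))
        heatmap = pd.DataFrame(
            {p.protein: p.relative for p in profiles}
        ).T.rename_axis("protein")
        heatmap.to_csv(out_dir / "deposition_relative.tsv", sep="\t", float_format=_FLOAT)
        outputs["deposition_relative"] = out_dir / "deposition_relative.tsv"

        stage = _stage("concordance")
        pop_means = nm.population_means(expr.EPITHELIAL_POPULATIONS)
        calls = []
        for p in profiles:
            if p.protein not in pop_means.index:
                continue
            calls.append(
                depo.concordance_call(
                    p.protein, pop_means.loc[p.protein], p.relative,
                    r_threshold=config.concordance_r,
                )
            )
        depo.concordance_table(calls).to_csv(
            out_dir / "concordance.tsv", sep="\t", index=False, float_format=_FLOAT
        )
        outputs["concordance"] = out_dir / "concordance.tsv"

        stage = _stage("manifest")
        manifest = {
            "config": asdict(config),
            "config_digest": config.digest(),
            "seed": config.seed,
            "package": "ecmatlas",
            "outputs": {
                name: _checksum(path) for name, path in outputs.items() if path.is_file()
            },
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        outputs["manifest"] = out_dir / "manifest.json"
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc
    return outputs


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
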