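"""End-to-end pipeline: simulate -> qc -> kinship -> pca -> diversity -> compare.

Each stage consumes the previous stage's outputs and writes plain-text
artifacts into its own subdirectory. A JSON manifest records the seed,
thresholds, per-stage record counts and a checksum per artifact, so a rerun
with the same configuration is bit-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .diversity import DEFAULT_ALPHA_GRID, DEFAULT_BETA_GRID, diversity_analysis
from .kinship import kinship_matrix
from .qc import FilterConfig, run_variant_qc
from .simulate import default_cohort, emit_cohort
from .stats import comparison_table
from .structure import pca_genotypes

log = logging.getLogger("hillpop")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "hillpop_run"
    vcf: str | None = None  # when None, the simulate stage provides inputs
    bed: str | None = None
    pop_map: str | None = None
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    group_level: str = "population"
    counting: str = "allele"
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "qc": True, "kinship": True,
            "pca": True, "diversity": True, "compare": True,
        }
    )
    simulate_options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        filters = FilterConfig(**raw.pop("filters", {}))
        stages = {**cls().stages, **raw.pop("stages", {})}
        for key in ("alpha_grid", "beta_grid"):
            if key in raw:
                raw[key] = tuple(float(q) for q in raw[key])
        return cls(filters=filters, stages=stages, **raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["artifacts"][str(path.relative_to(manifest["_root"]))] = {
        "sha256": _checksum(path),
        "n_records": len(df),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "filters": dataclasses.asdict(config.filters),
        "alpha_grid": list(config.alpha_grid),
        "beta_grid": list(config.beta_grid),
        "stages_enabled": dict(config.stages),
        "counts": {},
        "artifacts": {},
        "_root": out,
    }

    vcf, bed, pop_map = config.vcf, config.bed, config.pop_map
    if config.stages.get("simulate", True) and vcf is None:
        try:
            log.info("simulate: generating default synthetic cohort")
            cohort = default_cohort(seed=config.seed, **config.simulate_options)
            paths = emit_cohort(cohort, out / "simulate")
            vcf, bed, pop_map = (
                str(paths["vcf"]), str(paths["bed"]), str(paths["pop_map"])
            )
            for key, p in paths.items():
                manifest["artifacts"][str(p.relative_to(out))] = {
                    "sha256": _checksum(p)
                }
            manifest["counts"]["simulate"] = {
                "samples": cohort.genotypes.n_samples,
                "sites": cohort.genotypes.n_sites,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("simulate", e) from e
    if vcf is None or bed is None or pop_map is None:
        raise StageError(
            "input", ValueError("vcf, bed and pop_map required when simulate is off")
        )

    try:
        genotypes = hio.read_vcf(vcf)
        intervals = hio.read_bed(bed)
        popmap = hio.read_pop_map(pop_map)
    except Exception as e:  # noqa: BLE001
        raise StageError("input", e) from e

    diversity_genotypes = genotypes
    if config.stages.get("qc", True):
        try:
            log.info("qc: %d samples x %d sites in", genotypes.n_samples,
                     genotypes.n_sites)
            raw = genotypes
            genotypes, report = run_variant_qc(genotypes, config.filters)
            # Diversity profiles use the quality-filtered SNP set (hard
            # filters + depth + sample QC); the population filters (MAF,
            # call rate, HWE, LD) serve PCA and kinship.
            diversity_genotypes = raw.take_sites(
                report.quality_retained_sites
            ).take_samples(report.retained_samples)
            _write(report.to_frame(), out / "qc" / "filter_report.tsv", manifest)
            _write(
                genotypes.sites[["chrom", "pos"]],
                out / "qc" / "retained_sites.tsv",
                manifest,
            )
            _write(
                pd.DataFrame(report.excluded_samples,
                             columns=["sample", "reason"]),
                out / "qc" / "excluded_samples.tsv",
                manifest,
            )
            hio.write_vcf(genotypes, out / "qc" / "filtered.vcf")
            manifest["artifacts"]["qc/filtered.vcf"] = {
                "sha256": _checksum(out / "qc" / "filtered.vcf")
            }
            hio.write_vcf(diversity_genotypes, out / "qc" / "quality_filtered.vcf")
            manifest["artifacts"]["qc/quality_filtered.vcf"] = {
                "sha256": _checksum(out / "qc" / "quality_filtered.vcf")
            }
            manifest["counts"]["qc"] = {
                "samples": genotypes.n_samples, "sites": genotypes.n_sites
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("qc", e) from e

    if config.stages.get("kinship", True):
        try:
            pairs, summary = kinship_matrix(genotypes, popmap)
            _write(pairs, out / "kinship" / "pairwise.tsv", manifest)
            _write(summary, out / "kinship" / "summary.tsv", manifest)
            manifest["counts"]["kinship"] = {"pairs": len(pairs)}
        except Exception as e:  # noqa: BLE001
            raise StageError("kinship", e) from e

    if config.stages.get("pca", True):
        try:
            result = pca_genotypes(genotypes)
            scores = result.scores.reset_index(names="sample")
            _write(scores, out / "pca" / "scores.tsv", manifest)
            _write(
                pd.DataFrame(
                    {
                        "component": scores.columns[1:],
                        "variance_explained": result.variance_explained,
                    }
                ),
                out / "pca" / "variance_explained.tsv",
                manifest,
            )
            manifest["counts"]["pca"] = {
                "components": len(result.variance_explained)
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("pca", e) from e

    alpha_mean = None
    if config.stages.get("diversity", True):
        try:
            tables = diversity_analysis(
                diversity_genotypes, intervals, popmap,
                config.alpha_grid, config.beta_grid,
                level=config.group_level, counting=config.counting,
            )
            for name, df in tables.items():
                _write(df, out / "diversity" / f"{name}.tsv", manifest)
            alpha_mean = tables["alpha_mean"]
            manifest["counts"]["diversity"] = {
                name: len(df) for name, df in tables.items()
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("diversity", e) from e

    if config.stages.get("compare", True) and alpha_mean is not None:
        try:
            grouping = dict(
                zip(popmap.table["sample_id"], popmap.table[config.group_level])
            )
            grouping = {
                s: g for s, g in grouping.items() if s in genotypes.samples
            }
            comp = comparison_table(
                alpha_mean, grouping, value_col="alpha_mean", by=["q"]
            )
            _write(comp, out / "compare" / "alpha_comparisons.tsv", manifest)
            manifest["counts"]["compare"] = {"comparisons": len(comp)}
        except Exception as e:  # noqa: BLE001
            raise StageError("compare", e) from e

    manifest.pop("_root")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
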