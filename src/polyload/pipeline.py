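"""Orchestration: simulate -> analyze -> report with one config and seed.

``run_pipeline`` executes the full analysis (or a named subset of stages)
and writes a deterministic report directory: per-stage TSVs, a Newick tree,
and ``summary.json`` with the dataset-level AEI counts (genes with AEI per
fraction, their overlap, and genes flagged for a cytosol-vs-polysome
difference).  All randomness (simulation, bootstrap) flows from the single
config seed via named substreams, so two runs on the same config produce
byte-identical reports.  Progress and filter-attrition counts are logged to
stderr; the on-disk run log records only config, seed and version so the
report stays reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allelic import gene_aei_table, snp_ratio_table
from .formats import (
    read_allele_count_table,
    read_expression_table,
    read_mirna_count_table,
    read_target_map,
    write_results,
)
from .isoforms import cross_aei_isoforms, detect_isoform_shift, isoform_fractions
from .loading import class_composition, compare_ratio_distributions, loading_table, size_factors
from .mirna import mirna_loading_ratios, rank_consistent_mirnas, target_set_overlap
from .similarity import cluster_dendrogram, divergence_matrix, multinomial_bootstrap_ci
from .synthdata import SimParams, simulate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("polyload")

ALL_STAGES = ("allelic", "loading", "similarity", "isoforms", "mirna")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class InputPaths:
    allele_counts: Path | None = None
    expression: Path | None = None
    mirna_counts: Path | None = None
    target_map: Path | None = None


@dataclass
class RunConfig:
    """Thresholds, statistical settings and input source for one run.

    Exactly one of ``sim`` (simulate a dataset) or ``inputs`` (read tables
    from disk) must be set.
    """

    out_dir: Path = Path("polyload_report")
    sim: SimParams | None = None
    inputs: InputPaths | None = None
    min_reads: int = 20
    het_minor_fraction: float = 0.2
    aei_threshold: float = 2.0
    difference_threshold: float = 2.0
    isoform_min_shift: float = 0.20
    major_threshold: float = 0.5
    fpkm_pseudocount: float = 1.0
    mirna_pseudocount: float = 0.5
    alpha: float = 0.5
    n_boot: int = 200
    ci_level: float = 0.95
    linkage: str = "average"
    top_k: int = 20
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be configured")
        for name in (
            "min_reads", "aei_threshold", "difference_threshold",
            "isoform_min_shift", "major_threshold", "alpha", "n_boot",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        inputs = raw.pop("inputs", None)
        cfg = cls(**{k: v for k, v in raw.items() if k not in ("out_dir", "stages")})
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        if sim is not None:
            if "mirna_effect_range" in sim:
                sim["mirna_effect_range"] = tuple(sim["mirna_effect_range"])
            cfg.sim = SimParams(**sim)
        if inputs is not None:
            cfg.inputs = InputPaths(**{k: Path(v) for k, v in inputs.items()})
        return cfg

    def to_jsonable(self) -> dict:
        def conv(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, tuple):
                return list(v)
            return v

        # out_dir is where the report lands, not part of what it contains;
        # leaving it out keeps reports byte-identical across destinations.
        out = {
            k: conv(v)
            for k, v in vars(self).items()
            if k not in ("sim", "inputs", "out_dir")
        }
        if self.sim is not None:
            out["sim"] = {k: conv(v) for k, v in vars(self.sim).items()}
            out["sim"]["class_proportions"] = dict(self.sim.class_proportions)
        if self.inputs is not None:
            out["inputs"] = {k: conv(v) for k, v in vars(self.inputs).items()}
        return out


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        ds = simulate_dataset(config.sim)
        return ds.allele_counts, ds.expression, ds.mirna_counts, ds.target_map, ds.truth
    paths = config.inputs
    allele = read_allele_count_table(paths.allele_counts) if paths.allele_counts else None
    expr = read_expression_table(paths.expression) if paths.expression else None
    mir = read_mirna_count_table(paths.mirna_counts) if paths.mirna_counts else None
    tmap = read_target_map(paths.target_map) if paths.target_map else None
    return allele, expr, mir, tmap, None


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages and write a deterministic report directory."""
    config.validate()
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed, "version": __version__}
    tree_newick: str | None = None
    stage = "load"
    try:
        allele, expr, mir_counts, target_map, truth = _load_inputs(config)
        if config.sim is not None:
            from .synthdata import SimulatedDataset

            SimulatedDataset(expr, allele, mir_counts, target_map, truth).write(
                out_dir / "simulated_input"
            )

        aei = None
        if "allelic" in config.stages and allele is not None:
            stage = "allelic"
            snp = snp_ratio_table(
                allele,
                min_reads=config.min_reads,
                het_minor_fraction=config.het_minor_fraction,
            )
            attrition = snp["status"].value_counts().to_dict()
            logger.info("allelic: SNP filter attrition %s", attrition)
            aei = gene_aei_table(
                snp,
                aei_threshold=config.aei_threshold,
                difference_threshold=config.difference_threshold,
            )
            tables["snp_ratios"] = snp
            tables["aei"] = aei
            ok = aei[aei["status"] == "OK"]
            cyt_genes = set(ok.loc[ok["aei_cyt"], "gene_id"])
            poly_genes = set(ok.loc[ok["aei_poly"], "gene_id"])
            both = cyt_genes & poly_genes
            union = cyt_genes | poly_genes
            summary["allelic"] = {
                "snp_attrition": {k: int(v) for k, v in sorted(attrition.items())},
                "n_aei_genes_cytosol": len(cyt_genes),
                "n_aei_genes_polysome": len(poly_genes),
                "aei_overlap_percent": (100.0 * len(both) / len(union)) if union else 0.0,
                "n_difference_flagged_genes": int(
                    ok.loc[ok["difference_flag"], "gene_id"].nunique()
                ),
            }

        sf = None
        if expr is not None and ("loading" in config.stages or "isoforms" in config.stages):
            stage = "loading"
            sf = size_factors(expr.counts)
        if "loading" in config.stages and expr is not None:
            stage = "loading"
            load = loading_table(expr, sf, pseudo_fpkm=config.fpkm_pseudocount)
            comp = class_composition(expr, sf)
            tables["loading"] = load
            tables["class_composition"] = comp
            tables["size_factors"] = sf.rename_axis(["sample_id", "fraction"]).reset_index()
            coding = load.loc[load["rna_class"] == "protein_coding", "mean_L"]
            noncoding = load.loc[load["rna_class"] != "protein_coding", "mean_L"]
            if len(coding) >= 20 and len(noncoding) >= 20:
                chi2, df, p = compare_ratio_distributions(coding, noncoding)
                tables["ratio_dist_test"] = pd.DataFrame(
                    [{"comparison": "protein_coding_vs_noncoding", "chi2": chi2, "df": df, "p": p}]
                )
            summary["loading"] = {
                "n_features": int(len(load)),
                "n_significant_q_lt_0.05": int((load["q"] < 0.05).sum()),
            }

        if "similarity" in config.stages and mir_counts is not None:
            stage = "similarity"
            dm = divergence_matrix(mir_counts, alpha=config.alpha)
            tables["divergence_matrix"] = dm.rename_axis("sample").reset_index()
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(100,))
            )
            ci_rows = []
            cols = list(mir_counts.columns)
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    point, lo, hi = multinomial_bootstrap_ci(
                        mir_counts[cols[i]].to_numpy(),
                        mir_counts[cols[j]].to_numpy(),
                        alpha=config.alpha,
                        n_boot=config.n_boot,
                        level=config.ci_level,
                        seed=rng,
                    )
                    ci_rows.append(
                        {
                            "sample_a": f"{cols[i][0]}:{cols[i][1]}",
                            "sample_b": f"{cols[j][0]}:{cols[j][1]}",
                            "alpha": config.alpha,
                            "D": point,
                            "ci_lower": lo,
                            "ci_upper": hi,
                            "level": config.ci_level,
                            "n_boot": config.n_boot,
                        }
                    )
            tables["bootstrap_ci"] = pd.DataFrame(ci_rows)
            flat = dm.copy()
            flat.index = [f"{s}:{f}" for s, f in dm.index]
            flat.columns = flat.index
            _, tree_newick = cluster_dendrogram(flat, method=config.linkage)
            summary["similarity"] = {"alpha": config.alpha, "units": "nats"}

        if "isoforms" in config.stages and expr is not None:
            stage = "isoforms"
            usage = isoform_fractions(expr, sf)
            shifts = detect_isoform_shift(usage, min_shift=config.isoform_min_shift)
            tables["isoform_usage"] = usage
            tables["isoform_shifts"] = shifts
            summary["isoforms"] = {
                "n_isoforms": int(len(shifts)),
                "n_shifted": int(shifts["shift_flag"].sum()),
                "n_shifted_genes": int(shifts.loc[shifts["shift_flag"], "gene_id"].nunique()),
            }
            if aei is not None:
                cross = cross_aei_isoforms(
                    shifts, aei, major_only=True, major_threshold=config.major_threshold
                )
                tables["aei_isoform_cross"] = cross

        if "mirna" in config.stages and mir_counts is not None:
            stage = "mirna"
            enrich = mirna_loading_ratios(mir_counts, pseudocount=config.mirna_pseudocount)
            top_enr, top_dep = rank_consistent_mirnas(enrich, k=config.top_k)
            tables["mirna_enrichment"] = enrich
            tables["mirna_top_enriched"] = top_enr
            tables["mirna_top_depleted"] = top_dep
            summary["mirna"] = {
                "n_mirnas": int(len(enrich)),
                "n_enriched": int((enrich["consistency"] == "ENRICHED").sum()),
                "n_depleted": int((enrich["consistency"] == "DEPLETED").sum()),
            }
            if target_map is not None and "loading" in tables:
                load = tables["loading"]
                enriched_genes = set(
                    load.loc[(load["mean_L"] > 1.0) & (load["q"] < 0.05), "gene_id"]
                )
                per_mir, pooled = target_set_overlap(
                    {m: target_map[m] for m in top_enr["mir_id"] if m in target_map},
                    enriched_genes,
                )
                tables["target_overlap"] = per_mir
                summary["mirna"]["n_pooled_target_overlap"] = pooled

        stage = "report"
        write_results(tables, out_dir, tree_newick=tree_newick, summary=summary)
        log_lines = [
            f"polyload {__version__}",
            f"seed {config.seed}",
            "config " + json.dumps(config.to_jsonable(), sort_keys=True),
        ]
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except Exception as exc:  # partial outputs are removed on failure
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return out_dir
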