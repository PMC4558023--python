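"""Synthetic data with the statistical structure the polysome analysis assumes.

The generator emulates the count-level output of a cytosol / polysome
fractionation experiment on a handful of lymphoblast-like samples:

* allele read counts at 1-4 heterozygous SNPs per gene, binomially sampled
  from the gene's true allelic fraction over negative-binomial sequencing
  depths, with genomic-DNA counts at the same sites centred on 0.5;
* a feature x (sample, fraction) count matrix in which each gene carries a
  class-dependent polysome-loading coefficient lambda (long noncoding RNA
  and pseudogene classes shifted below 1), Dirichlet isoform usage with
  fraction-specific shifts for a subset of multi-isoform genes, and
  per-sample biological noise that is wider in the cytosol than on
  polysomes (polysomal occupancy being the more tightly regulated quantity);
* microRNA libraries in which each microRNA has a true polysome/cytosol
  enrichment factor;
* a microRNA -> target-gene map biased toward polysome-enriched targets.

Genes are partitioned into a null group (both fractions balanced), an
expression-AEI group (the same allelic imbalance in both fractions), and a
loading-AEI group (balanced in the cytosol, imbalanced on polysomes), so
that the cross-fraction difference statistic isolates the loading effect.
Every simulated quantity is recorded in a :class:`TruthTable` for recovery
tests.  All randomness flows from a single seed through named substreams,
so identical parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .formats import (
    ExpressionMatrix,
    write_allele_count_table,
    write_expression_table,
    write_mirna_count_table,
)

__all__ = [
    "SimParams",
    "TruthTable",
    "SimulatedDataset",
    "simulate_allele_counts",
    "simulate_expression_counts",
    "simulate_mirna_counts",
    "simulate_dataset",
]

_DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "protein_coding": 0.70,
    "pseudogene": 0.12,
    "lncRNA_antisense": 0.05,
    "lincRNA": 0.02,
    "lncRNA_other": 0.08,
    "other": 0.03,
}

# Mean log2 polysome/cytosol loading coefficient per RNA class: noncoding
# classes are depleted on polysomes, antisense RNA least so.
_CLASS_LOG2_LAMBDA: dict[str, float] = {
    "protein_coding": 0.0,
    "pseudogene": -1.0,
    "lncRNA_antisense": -0.5,
    "lincRNA": -1.5,
    "lncRNA_other": -2.0,
    "other": 0.0,
}


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Effects are ratios >= 1: ``expression_effect`` is the true major/minor
    allelic ratio of cis-regulated genes in both fractions;
    ``loading_effect`` is the polysome/cytosol ratio-of-ratios of genes whose
    variant acts on loading only.  ``isoform_shift_delta`` is an absolute
    usage-fraction shift of a gene's top isoform between fractions.
    """

    n_genes: int = 500
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROPORTIONS)
    )
    n_samples: int = 3
    depth_mean_rna: float = 200.0
    depth_mean_gdna: float = 200.0
    nb_dispersion: float = 10.0          # NB size parameter; larger = closer to Poisson
    pi_aei_expression: float = 0.10
    pi_aei_loading: float = 0.10
    expression_effect: float = 2.0
    loading_effect: float = 4.0
    isoform_shift_delta: float = 0.30
    pi_isoform_shift: float = 0.15
    mirna_effect_range: tuple[float, float] = (0.1, 10.0)
    n_mirnas: int = 150
    mirna_library_depth: float = 1.0e5
    mean_expression: float = 300.0       # median gene-level counts per library
    expression_sigma: float = 1.0        # lognormal sd of gene means (log scale)
    sample_sigma_cyt: float = 0.4        # per-sample biological noise, cytosol
    sample_sigma_poly: float = 0.1       # per-sample biological noise, polysome
    min_snps_per_gene: int = 1
    max_snps_per_gene: int = 4
    max_isoforms_per_gene: int = 3
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.class_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if any(v < 0 for v in props.values()):
            raise ValueError("class_proportions must be non-negative")
        for name in ("pi_aei_expression", "pi_aei_loading", "pi_isoform_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pi_aei_expression + self.pi_aei_loading > 1.0:
            raise ValueError("pi_aei_expression + pi_aei_loading must be <= 1")
        if self.expression_effect < 1.0 or self.loading_effect < 1.0:
            raise ValueError("effects are ratios >= 1")
        if not 0.0 <= self.isoform_shift_delta <= 1.0:
            raise ValueError("isoform_shift_delta must be in [0, 1]")
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        if not 1 <= self.min_snps_per_gene <= self.max_snps_per_gene:
            raise ValueError("need 1 <= min_snps_per_gene <= max_snps_per_gene")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        if "mirna_effect_range" in raw:
            raw["mirna_effect_range"] = tuple(raw["mirna_effect_range"])
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset.

    ``genes``: gene_id, rna_class, group (null / expression_aei /
    loading_aei), p_cyt, p_poly (true reference-allele fractions), lam
    (polysome/cytosol loading coefficient), mu (mean cytosol counts),
    n_snps, n_isoforms, isoform_shifted.
    ``isoforms``: isoform_id, gene_id, usage_cyt, usage_poly, shifted.
    ``mirnas``: mir_id, enrichment (true polysome/cytosol factor).
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    mirnas: pd.DataFrame


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    allele_counts: pd.DataFrame
    mirna_counts: pd.DataFrame
    target_map: dict[str, set[str]]
    truth: TruthTable

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_allele_count_table(self.allele_counts, out_dir / "allele_counts.tsv")
        write_expression_table(self.expression, out_dir / "expression.tsv")
        write_mirna_count_table(self.mirna_counts, out_dir / "mirna_counts.tsv")
        rows = [
            {"mir_id": m, "gene_id": g}
            for m in sorted(self.target_map)
            for g in sorted(self.target_map[m])
        ]
        pd.DataFrame(rows, columns=["mir_id", "gene_id"]).to_csv(
            out_dir / "target_map.tsv", sep="\t", index=False, lineterminator="\n"
        )
        self.truth.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False, lineterminator="\n")
        self.truth.isoforms.to_csv(out_dir / "truth_isoforms.tsv", sep="\t", index=False, lineterminator="\n")
        self.truth.mirnas.to_csv(out_dir / "truth_mirnas.tsv", sep="\t", index=False, lineterminator="\n")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial depths with the given mean and size parameter."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_allele_counts(
    p_true: float,
    depth_mean: float,
    n_snps: int,
    dispersion: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Allele counts at ``n_snps`` SNPs sharing one true reference fraction.

    Depth per SNP is negative-binomial with the given mean and dispersion;
    the reference count is Binomial(depth, p_true).  Returns a DataFrame
    with columns snp_id, ref_count, alt_count.
    """
    if not 0.0 < p_true < 1.0:
        raise ValueError("p_true must lie strictly between 0 and 1")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depths = _nb_depths(rng, depth_mean, dispersion, n_snps)
    ref = rng.binomial(depths, p_true)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n_snps)],
            "ref_count": ref,
            "alt_count": depths - ref,
        }
    )


def _make_truth(params: SimParams) -> TruthTable:
    """Assign classes, AEI groups, loading coefficients and isoform usage."""
    rng = _rng(params.seed, 0)
    n = params.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    classes = sorted(params.class_proportions)
    props = np.array([params.class_proportions[c] for c in classes], dtype=float)
    rna_class = rng.choice(classes, size=n, p=props / props.sum())

    # Deterministic group sizes, randomized membership.
    n_load = int(round(params.pi_aei_loading * n))
    n_expr = int(round(params.pi_aei_expression * n))
    order = rng.permutation(n)
    group = np.full(n, "null", dtype=object)
    group[order[:n_load]] = "loading_aei"
    group[order[n_load : n_load + n_expr]] = "expression_aei"

    rho_e = params.expression_effect
    rho_l = params.loading_effect
    p_cyt = np.where(group == "expression_aei", rho_e / (1.0 + rho_e), 0.5)
    p_poly = np.where(
        group == "expression_aei",
        rho_e / (1.0 + rho_e),
        np.where(group == "loading_aei", rho_l / (1.0 + rho_l), 0.5),
    )

    shift = np.array([_CLASS_LOG2_LAMBDA[c] for c in rna_class])
    lam = 2.0 ** rng.normal(shift, 0.5)
    mu = params.mean_expression * np.exp(
        rng.normal(0.0, params.expression_sigma, n) - params.expression_sigma**2 / 2
    )
    n_snps = rng.integers(params.min_snps_per_gene, params.max_snps_per_gene + 1, size=n)
    n_isoforms = rng.integers(1, params.max_isoforms_per_gene + 1, size=n)

    multi = np.flatnonzero(n_isoforms >= 2)
    n_shift = int(round(params.pi_isoform_shift * len(multi)))
    shifted_genes = set(rng.permutation(multi)[:n_shift])
    isoform_shifted = np.array([i in shifted_genes for i in range(n)])

    delta = params.isoform_shift_delta
    iso_rows = []
    for i in range(n):
        k = int(n_isoforms[i])
        if k == 1:
            usage_c = np.array([1.0])
        else:
            # Top isoform needs headroom to give away delta; the runner-up
            # needs headroom to receive it.
            for _ in range(1000):
                usage_c = np.sort(rng.dirichlet(np.full(k, 5.0)))[::-1]
                if not isoform_shifted[i]:
                    break
                if usage_c[0] - delta >= 0.02 and usage_c[1] + delta <= 0.98:
                    break
            else:  # pragma: no cover - delta near 1 with tiny headroom
                raise ValueError("could not draw isoform usage compatible with delta")
        usage_p = usage_c.copy()
        if isoform_shifted[i]:
            usage_p[0] -= delta
            usage_p[1] += delta
        lengths = rng.integers(500, 3000, size=k)
        for j in range(k):
            iso_rows.append(
                {
                    "isoform_id": f"{gene_ids[i]}.t{j}",
                    "gene_id": gene_ids[i],
                    "length_bases": int(lengths[j]),
                    "usage_cyt": usage_c[j],
                    "usage_poly": usage_p[j],
                    "shifted": bool(isoform_shifted[i]),
                }
            )

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "rna_class": rna_class,
            "group": group,
            "p_cyt": p_cyt,
            "p_poly": p_poly,
            "lam": lam,
            "mu": mu,
            "n_snps": n_snps,
            "n_isoforms": n_isoforms,
            "isoform_shifted": isoform_shifted,
        }
    )

    lo, hi = params.mirna_effect_range
    mir_rng = _rng(params.seed, 1)
    enrichment = np.exp(mir_rng.uniform(np.log(lo), np.log(hi), params.n_mirnas))
    mirnas = pd.DataFrame(
        {
            "mir_id": [f"mir{i:04d}" for i in range(params.n_mirnas)],
            "enrichment": enrichment,
        }
    )
    return TruthTable(genes=genes, isoforms=pd.DataFrame(iso_rows), mirnas=mirnas)


def simulate_expression_counts(
    params: SimParams, truth: TruthTable, seed: int | None = None
) -> ExpressionMatrix:
    """Isoform-level counts for every (sample, fraction) library.

    Gene counts are negative-binomial around mu (cytosol) and mu * lambda
    (polysome), with lognormal per-sample noise that is wider in the cytosol
    than on polysomes.  True usage is a molar (transcript) share, so isoform
    read counts split the gene count multinomially with probability
    proportional to usage x isoform length; FPKM-based usage estimates then
    recover the truth.
    """
    rng = _rng(params.seed if seed is None else seed, 2)
    genes = truth.genes
    iso = truth.isoforms
    samples = [f"S{j + 1}" for j in range(params.n_samples)]

    features = pd.DataFrame(
        {
            "gene_id": iso["gene_id"].to_numpy(),
            "rna_class": genes.set_index("gene_id").loc[iso["gene_id"], "rna_class"].to_numpy(),
            "length_bases": iso["length_bases"].to_numpy(),
        },
        index=pd.Index(iso["isoform_id"], name="feature_id"),
    )

    usage = {"CYTOSOL": "usage_cyt", "POLYSOME": "usage_poly"}
    gene_index = {g: np.flatnonzero(iso["gene_id"].to_numpy() == g) for g in genes["gene_id"]}
    counts = pd.DataFrame(
        0, index=features.index, columns=pd.MultiIndex.from_product(
            [samples, ["CYTOSOL", "POLYSOME"]], names=["sample_id", "fraction"]
        )
    )
    sigma = {"CYTOSOL": params.sample_sigma_cyt, "POLYSOME": params.sample_sigma_poly}
    mu_frac = {
        "CYTOSOL": genes["mu"].to_numpy(),
        "POLYSOME": genes["mu"].to_numpy() * genes["lam"].to_numpy(),
    }
    for sample in samples:
        for fraction in ("CYTOSOL", "POLYSOME"):
            s = sigma[fraction]
            noise = np.exp(rng.normal(0.0, s, len(genes)) - s**2 / 2)
            mean = np.maximum(mu_frac[fraction] * noise, 1e-9)
            p = params.nb_dispersion / (params.nb_dispersion + mean)
            gene_counts = rng.negative_binomial(params.nb_dispersion, p)
            col = np.zeros(len(iso), dtype=np.int64)
            usage_col = iso[usage[fraction]].to_numpy() * iso["length_bases"].to_numpy()
            for gi, g in enumerate(genes["gene_id"]):
                idx = gene_index[g]
                u = usage_col[idx]
                col[idx] = rng.multinomial(gene_counts[gi], u / u.sum())
            counts[(sample, fraction)] = col
    return ExpressionMatrix(features, counts)


def simulate_mirna_counts(params: SimParams, truth: TruthTable, seed: int | None = None) -> pd.DataFrame:
    """microRNA counts per (sample, fraction) library.

    Cytosol composition is a lognormal baseline per microRNA; the polysome
    composition multiplies it by the true enrichment factor.  Per-sample
    noise is wider in the cytosol, and library totals are negative-binomial
    around ``mirna_library_depth``.
    """
    rng = _rng(params.seed if seed is None else seed, 4)
    mirs = truth.mirnas
    base = np.exp(rng.normal(0.0, 1.5, len(mirs)))
    samples = [f"S{j + 1}" for j in range(params.n_samples)]
    counts = pd.DataFrame(
        0,
        index=pd.Index(mirs["mir_id"], name="mir_id"),
        columns=pd.MultiIndex.from_product(
            [samples, ["CYTOSOL", "POLYSOME"]], names=["sample_id", "fraction"]
        ),
    )
    sigma = {"CYTOSOL": params.sample_sigma_cyt, "POLYSOME": params.sample_sigma_poly}
    for sample in samples:
        for fraction in ("CYTOSOL", "POLYSOME"):
            s = sigma[fraction]
            w = base * np.exp(rng.normal(0.0, s, len(mirs)) - s**2 / 2)
            if fraction == "POLYSOME":
                w = w * mirs["enrichment"].to_numpy()
            depth = int(
                _nb_depths(rng, params.mirna_library_depth, params.nb_dispersion, 1)[0]
            )
            counts[(sample, fraction)] = rng.multinomial(depth, w / w.sum())
    return counts


def _simulate_gene_allele_counts(params: SimParams, truth: TruthTable) -> pd.DataFrame:
    rng = _rng(params.seed, 5)
    rows = []
    samples = [f"S{j + 1}" for j in range(params.n_samples)]
    p_by_fraction = {"CYTOSOL": "p_cyt", "POLYSOME": "p_poly"}
    for g in truth.genes.itertuples(index=False):
        for k in range(int(g.n_snps)):
            snp_id = f"{g.gene_id}_snp{k}"
            for sample in samples:
                for fraction, col in p_by_fraction.items():
                    depth = int(_nb_depths(rng, params.depth_mean_rna, params.nb_dispersion, 1)[0])
                    ref = int(rng.binomial(depth, getattr(g, col)))
                    rows.append((sample, fraction, g.gene_id, snp_id, ref, depth - ref))
                depth = int(_nb_depths(rng, params.depth_mean_gdna, params.nb_dispersion, 1)[0])
                ref = int(rng.binomial(depth, 0.5))
                rows.append((sample, "GDNA", g.gene_id, snp_id, ref, depth - ref))
    return pd.DataFrame(
        rows, columns=["sample_id", "fraction", "gene_id", "snp_id", "ref_count", "alt_count"]
    )


def _make_target_map(params: SimParams, truth: TruthTable) -> dict[str, set[str]]:
    """Map each microRNA to target genes, biased so that polysome-enriched
    microRNAs preferentially target polysome-enriched genes."""
    rng = _rng(params.seed, 6)
    genes = truth.genes
    lam = genes["lam"].to_numpy()
    gene_ids = genes["gene_id"].to_numpy()
    out: dict[str, set[str]] = {}
    for mir, factor in zip(truth.mirnas["mir_id"], truth.mirnas["enrichment"]):
        k = int(rng.integers(5, 21))
        w = lam if factor > 1.0 else np.ones_like(lam)
        w = w / w.sum()
        idx = rng.choice(len(gene_ids), size=min(k, len(gene_ids)), replace=False, p=w)
        out[mir] = set(gene_ids[idx])
    return out


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Generate a full dataset (expression, allele counts incl. gDNA,
    microRNA counts, target map) together with its ground truth."""
    params.validate()
    truth = _make_truth(params)
    expression = simulate_expression_counts(params, truth)
    allele_counts = _simulate_gene_allele_counts(params, truth)
    mirna_counts = simulate_mirna_counts(params, truth)
    target_map = _make_target_map(params, truth)
    return SimulatedDataset(
        expression=expression,
        allele_counts=allele_counts,
        mirna_counts=mirna_counts,
        target_map=target_map,
        truth=truth,
    )
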