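"""Allelic ratio estimation and allele-selective polysome-loading calls.

The readout at each heterozygous SNP is the RNA reference/alternative read
ratio normalized to the genomic-DNA ratio of the same site (gDNA set to 1.0
corrects assay bias).  SNPs pass only with at least ``min_reads`` RNA reads;
sites whose gDNA counts look homozygous are rejected; sites where one RNA
allele is absent are excluded as monoallelic by default (an optional
pseudocount mode keeps them with +0.5 on both alleles).

Gene-level ratios average the SNP ratios of a transcript after orienting
every SNP so that the same physical allele sits in the numerator across
fractions.  No phasing is available, so each SNP is oriented by the
fraction where its ratio deviates most from 1 (the most informative
fraction): if that ratio is < 1 the SNP is inverted in all fractions.
Anchoring on the strongest fraction keeps the orientation consistent
across a transcript's SNPs when the imbalance lives in only one fraction
(e.g. allele-selective loading with a balanced cytosol), where a
cytosol-only anchor would flip SNPs at random.  SNPs lacking a passing
cytosol ratio are dropped, and genes without any passing cytosol SNP are
skipped.  Two statistics follow:

* M = max(r, 1/r), the allelic-imbalance magnitude; M >= 2 flags AEI.
* D = max(r_cyt/r_poly, r_poly/r_cyt), the cytosol-vs-polysome fold
  difference; because both ratios are identically oriented, a reversal of
  allele dominance between fractions compounds (cytosol 0.5 vs polysome 2
  gives D = 4), and D >= 2 flags allele-selective polysome loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import GDNA

__all__ = [
    "PASS",
    "LOW_READS",
    "NOT_HET",
    "MONOALLELIC",
    "snp_ratio",
    "snp_ratio_table",
    "gene_ratio",
    "call_aei",
    "aei_fraction_difference",
    "gene_aei_table",
]

PASS = "PASS"
LOW_READS = "LOW_READS"
NOT_HET = "NOT_HET"
MONOALLELIC = "MONOALLELIC"


@dataclass(frozen=True)
class SnpRatio:
    snp_id: str
    sample_id: str
    fraction: str
    r: float  # gDNA-normalized ref/alt ratio; NaN unless status == PASS
    total_reads: int
    status: str


def snp_ratio(
    rna_ref: int,
    rna_alt: int,
    gdna_ref: int,
    gdna_alt: int,
    min_reads: int = 20,
    het_minor_fraction: float = 0.2,
    pseudocount: bool = False,
) -> tuple[float, str]:
    """gDNA-normalized allelic ratio of one SNP in one RNA library.

    Returns ``(r, status)``; ``r`` is NaN unless the status is PASS.
    """
    for v in (rna_ref, rna_alt, gdna_ref, gdna_alt):
        if v < 0:
            raise ValueError("allele counts must be non-negative")
    rna_total = rna_ref + rna_alt
    gdna_total = gdna_ref + gdna_alt
    if rna_total < min_reads:
        return float("nan"), LOW_READS
    if gdna_total < min_reads or min(gdna_ref, gdna_alt) / gdna_total < het_minor_fraction:
        return float("nan"), NOT_HET
    if rna_ref == 0 or rna_alt == 0:
        if not pseudocount:
            return float("nan"), MONOALLELIC
        rna_ref, rna_alt = rna_ref + 0.5, rna_alt + 0.5
    r = (rna_ref / rna_alt) / (gdna_ref / gdna_alt)
    return r, PASS


def snp_ratio_table(
    allele_counts: pd.DataFrame,
    min_reads: int = 20,
    het_minor_fraction: float = 0.2,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Per-SNP gDNA-normalized ratios for every RNA (sample, fraction) row.

    ``allele_counts`` is the long-format table of
    :func:`polyload.formats.read_allele_count_table`, with gDNA rows under
    the GDNA pseudo-fraction.  gDNA is matched per (sample, snp); RNA rows
    without a gDNA row for their sample are reported NOT_HET.
    """
    gdna = allele_counts[allele_counts["fraction"] == GDNA]
    gdna_map = {
        (s, snp): (int(rc), int(ac))
        for s, snp, rc, ac in zip(
            gdna["sample_id"], gdna["snp_id"], gdna["ref_count"], gdna["alt_count"]
        )
    }
    rna = allele_counts[allele_counts["fraction"] != GDNA]
    rows = []
    for rec in rna.itertuples(index=False):
        g = gdna_map.get((rec.sample_id, rec.snp_id))
        if g is None:
            r, status = float("nan"), NOT_HET
        else:
            r, status = snp_ratio(
                rec.ref_count,
                rec.alt_count,
                g[0],
                g[1],
                min_reads=min_reads,
                het_minor_fraction=het_minor_fraction,
                pseudocount=pseudocount,
            )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "fraction": rec.fraction,
                "gene_id": rec.gene_id,
                "snp_id": rec.snp_id,
                "r": r,
                "total_reads": rec.ref_count + rec.alt_count,
                "status": status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "fraction", "gene_id", "snp_id", "r", "total_reads", "status"],
    )


def gene_ratio(
    snp_ratios: pd.DataFrame, anchor_fraction: str = "CYTOSOL"
) -> dict[str, tuple[float, float, int]]:
    """Oriented mean ratio per fraction for one gene in one sample.

    ``snp_ratios`` holds the PASS SNP rows of a single (gene, sample) with
    columns snp_id, fraction, r.  Each SNP is oriented by its most
    informative fraction: among the SNP's PASS ratios, the one with the
    largest |ln r| decides, and if it is < 1 the SNP is inverted in every
    fraction.  SNPs without a PASS ratio in ``anchor_fraction`` are dropped
    (the cross-fraction comparison needs the cytosol side), and a gene with
    no PASS SNP there raises ``ValueError``.  Returns
    ``{fraction: (mean, sd, n_snps)}`` with the sample standard deviation
    over SNPs (0 when n = 1).
    """
    passing = snp_ratios[np.isfinite(snp_ratios["r"])]
    anchor = passing[passing["fraction"] == anchor_fraction]
    if anchor.empty:
        raise ValueError(f"no PASS SNP in anchor fraction {anchor_fraction!r}")
    anchored_snps = set(anchor["snp_id"])
    invert: dict = {}
    for snp, grp in passing.groupby("snp_id", sort=True):
        if snp not in anchored_snps:
            continue
        r_vals = grp["r"].to_numpy(dtype=float)
        strongest = r_vals[np.abs(np.log(r_vals)).argmax()]
        invert[snp] = strongest < 1.0
    out: dict[str, tuple[float, float, int]] = {}
    for fraction, grp in passing.groupby("fraction", sort=True):
        grp = grp[grp["snp_id"].isin(invert)]
        if grp.empty:
            continue
        oriented = np.array(
            [1.0 / r if invert[snp] else r for snp, r in zip(grp["snp_id"], grp["r"])]
        )
        mean = float(oriented.mean())
        sd = float(oriented.std(ddof=1)) if len(oriented) > 1 else 0.0
        out[str(fraction)] = (mean, sd, len(oriented))
    return out


def call_aei(r_bar: float, threshold: float = 2.0) -> tuple[float, bool]:
    """AEI magnitude M = max(r, 1/r) and its >= threshold flag."""
    if not r_bar > 0:
        raise ValueError("mean allelic ratio must be positive")
    m = max(r_bar, 1.0 / r_bar)
    return m, m >= threshold


def aei_fraction_difference(
    r_cyt: float, r_poly: float, threshold: float = 2.0
) -> tuple[float, bool]:
    """Cross-fraction fold difference D = max(r_cyt/r_poly, r_poly/r_cyt).

    Both ratios must be identically oriented; dominance reversal between
    fractions therefore compounds (0.5 vs 2.0 gives D = 4.0).
    """
    if not (r_cyt > 0 and r_poly > 0):
        raise ValueError("oriented ratios must be positive")
    d = max(r_cyt / r_poly, r_poly / r_cyt)
    return d, d >= threshold


def gene_aei_table(
    snp_ratios: pd.DataFrame,
    aei_threshold: float = 2.0,
    difference_threshold: float = 2.0,
    cytosol: str = "CYTOSOL",
    polysome: str = "POLYSOME",
) -> pd.DataFrame:
    """Gene x sample AEI table with per-fraction means, M, D and flags.

    Genes without a PASS cytosol SNP in a sample are reported with status
    ``NO_ANCHOR`` and no ratios; genes with a cytosol mean but no polysome
    mean get status ``NO_POLYSOME`` and an undefined D.
    """
    rows = []
    for (gene, sample), grp in snp_ratios.groupby(["gene_id", "sample_id"], sort=True):
        row: dict = {"gene_id": gene, "sample_id": sample}
        try:
            per_fraction = gene_ratio(grp, anchor_fraction=cytosol)
        except ValueError:
            row.update(
                r_cyt=np.nan, sd_cyt=np.nan, n_snp_cyt=0,
                r_poly=np.nan, sd_poly=np.nan, n_snp_poly=0,
                M_cyt=np.nan, M_poly=np.nan, D=np.nan,
                aei_cyt=False, aei_poly=False, difference_flag=False,
                status="NO_ANCHOR",
            )
            rows.append(row)
            continue
        r_c, sd_c, n_c = per_fraction[cytosol]
        m_c, flag_c = call_aei(r_c, aei_threshold)
        if polysome in per_fraction:
            r_p, sd_p, n_p = per_fraction[polysome]
            m_p, flag_p = call_aei(r_p, aei_threshold)
            d, dflag = aei_fraction_difference(r_c, r_p, difference_threshold)
            status = "OK"
        else:
            r_p = sd_p = m_p = d = np.nan
            n_p, flag_p, dflag = 0, False, False
            status = "NO_POLYSOME"
        row.update(
            r_cyt=r_c, sd_cyt=sd_c, n_snp_cyt=n_c,
            r_poly=r_p, sd_poly=sd_p, n_snp_poly=n_p,
            M_cyt=m_c, M_poly=m_p, D=d,
            aei_cyt=flag_c, aei_poly=flag_p, difference_flag=dflag,
            status=status,
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id",
            "r_cyt", "sd_cyt", "n_snp_cyt",
            "r_poly", "sd_poly", "n_snp_poly",
            "M_cyt", "M_poly", "D",
            "aei_cyt", "aei_poly", "difference_flag", "status",
        ],
    )
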