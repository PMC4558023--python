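"""Isoform usage per cellular fraction and shift detection.

An isoform's usage f is its share of the gene's summed FPKM within a
(sample, fraction) library; usages sum to 1 per gene per library.  The
shift statistic is Delta = f_polysome - f_cytosol, averaged across samples
(a strict mode instead requires the flag in every sample); |Delta| above
``min_shift`` (default 0.20, an absolute usage change of 20 percentage
points) flags the isoform as polysome-enriched (Delta > 0) or depleted.
Flagged isoforms are cross-tabulated with the gene's allelic ratios, with
an optional restriction to major isoforms (usage > 0.5 in either fraction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix
from .loading import fpkm_matrix

__all__ = ["isoform_fractions", "detect_isoform_shift", "cross_aei_isoforms"]


def isoform_fractions(
    expr: ExpressionMatrix,
    size: pd.Series | None = None,
    cytosol: str = "CYTOSOL",
    polysome: str = "POLYSOME",
) -> pd.DataFrame:
    """Per-isoform usage fractions in every (sample, fraction) library.

    Returns a long table with columns isoform_id, gene_id, sample_id,
    fraction, f.  Genes whose summed FPKM is zero in a library are skipped
    there (usage undefined).
    """
    fk = fpkm_matrix(expr, size)
    gene_ids = expr.features["gene_id"]
    rows = []
    for col in fk.columns:
        gene_sum = fk[col].groupby(gene_ids, sort=False).transform("sum")
        ok = gene_sum > 0
        f = fk[col][ok] / gene_sum[ok]
        for iso, g, val in zip(f.index, gene_ids[ok], f.to_numpy()):
            rows.append(
                {
                    "isoform_id": iso,
                    "gene_id": g,
                    "sample_id": col[0],
                    "fraction": col[1],
                    "f": val,
                }
            )
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "sample_id", "fraction", "f"])


def detect_isoform_shift(
    usage: pd.DataFrame,
    min_shift: float = 0.20,
    mode: str = "mean",
    cytosol: str = "CYTOSOL",
    polysome: str = "POLYSOME",
) -> pd.DataFrame:
    """Flag isoforms whose usage shifts between cytosol and polysomes.

    ``usage`` is the long table of :func:`isoform_fractions`.  In ``mean``
    mode, per-sample usages are averaged per fraction before thresholding
    (consistency across replicates); in ``strict`` mode the |Delta| >
    min_shift criterion must hold in every sample.  Returns one row per
    isoform observed in both fractions: isoform_id, gene_id, f_cyt, f_poly
    (mean usages), delta, shift_flag, direction (polysome_enriched /
    polysome_depleted / none), major_flag (mean usage > 0.5 in either
    fraction).
    """
    if mode not in ("mean", "strict"):
        raise ValueError("mode must be 'mean' or 'strict'")
    wide = usage.pivot_table(
        index=["isoform_id", "gene_id", "sample_id"], columns="fraction", values="f"
    )
    if cytosol not in wide.columns or polysome not in wide.columns:
        raise ValueError("usage must cover both fractions")
    wide = wide.dropna(subset=[cytosol, polysome])
    rows = []
    for (iso, gene), grp in wide.groupby(level=["isoform_id", "gene_id"], sort=True):
        f_c = float(grp[cytosol].mean())
        f_p = float(grp[polysome].mean())
        delta = f_p - f_c
        if mode == "mean":
            flag = abs(delta) > min_shift
        else:
            per_sample = grp[polysome] - grp[cytosol]
            flag = bool((per_sample.abs() > min_shift).all()) and len(per_sample) > 0
        direction = "none"
        if flag:
            direction = "polysome_enriched" if delta > 0 else "polysome_depleted"
        rows.append(
            {
                "isoform_id": iso,
                "gene_id": gene,
                "f_cyt": f_c,
                "f_poly": f_p,
                "delta": delta,
                "shift_flag": flag,
                "direction": direction,
                "major_flag": max(f_c, f_p) > 0.5,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "isoform_id", "gene_id", "f_cyt", "f_poly",
            "delta", "shift_flag", "direction", "major_flag",
        ],
    )


def cross_aei_isoforms(
    shifts: pd.DataFrame,
    aei: pd.DataFrame,
    major_only: bool = True,
    major_threshold: float = 0.5,
) -> pd.DataFrame:
    """Join flagged shifted isoforms with their gene's allelic ratios.

    ``shifts`` comes from :func:`detect_isoform_shift`; ``aei`` is the
    gene-level table of :func:`polyload.allelic.gene_aei_table`.  One row
    per (flagged isoform, sample) with the gene's oriented cytosol/polysome
    ratios, D, and an aei_class of ``aei_with_fraction_difference`` or
    ``aei_without_fraction_difference``.  With ``major_only`` the join is
    restricted to isoforms whose usage exceeds ``major_threshold`` in
    either fraction.
    """
    flagged = shifts[shifts["shift_flag"]]
    if major_only:
        flagged = flagged[
            np.maximum(flagged["f_cyt"], flagged["f_poly"]) > major_threshold
        ]
    usable = aei[aei["status"] == "OK"]
    merged = flagged.merge(usable, on="gene_id", how="inner")
    merged["aei_class"] = np.where(
        merged["difference_flag"],
        "aei_with_fraction_difference",
        "aei_without_fraction_difference",
    )
    cols = [
        "isoform_id", "gene_id", "sample_id", "f_cyt", "f_poly", "delta",
        "direction", "r_cyt", "r_poly", "D", "difference_flag", "aei_class",
    ]
    return merged[cols].sort_values(["isoform_id", "sample_id"]).reset_index(drop=True)
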