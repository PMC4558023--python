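"""Abundance normalization and polysome/cytosol loading profiles.

FPKM (fragments per kilobase of feature per million mapped reads) is the
abundance unit; effective library sizes come from the median-of-ratios
estimator (each library's median ratio to the per-feature geometric mean
row, rescaled to geometric mean 1).  Per-feature loading is the per-sample
log2 fold change L = log2((FPKM_poly + c0)/(FPKM_cyt + c0)) with a
pseudo-FPKM c0 bounding dropouts; differential loading across the paired
replicate design is a two-sided one-sample t-test of mean L against 0 with
Benjamini-Hochberg correction across features.

Class-level views: percentage of summed FPKM per RNA class per library, and
a chi-squared homogeneity test comparing the distributions of log2 loading
ratios of two RNA classes over shared bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix

__all__ = [
    "fpkm",
    "fpkm_matrix",
    "size_factors",
    "loading_table",
    "paired_loading_test",
    "class_composition",
    "compare_ratio_distributions",
]


def fpkm(counts, length_bases, library_size: float):
    """FPKM_i = counts_i * 1e9 / (length_i * library_size)."""
    counts = np.asarray(counts, dtype=float)
    length_bases = np.asarray(length_bases, dtype=float)
    if np.any(length_bases <= 0):
        raise ValueError("feature lengths must be positive")
    if not library_size > 0:
        raise ValueError("library size must be positive")
    return counts * 1.0e9 / (length_bases * library_size)


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios effective library-size factors per column.

    Only features with nonzero counts in every column enter the reference
    geometric mean; the factors are rescaled to geometric mean 1.
    """
    mat = count_matrix.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature with nonzero counts in every column")
    sub = mat[nonzero]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def fpkm_matrix(expr: ExpressionMatrix, size: pd.Series | None = None) -> pd.DataFrame:
    """FPKM per feature per (sample, fraction) column.

    Without size factors the library size is the column total; with them it
    is the geometric-mean raw total scaled by each column's factor, so the
    factors carry all between-library normalization.
    """
    totals = expr.counts.sum(axis=0).astype(float)
    if size is None:
        lib = totals
    else:
        lib = pd.Series(
            np.exp(np.mean(np.log(totals.to_numpy()))) * size.reindex(totals.index).to_numpy(),
            index=totals.index,
        )
    lengths = expr.features["length_bases"].to_numpy(dtype=float)
    out = {}
    for col in expr.counts.columns:
        out[col] = fpkm(expr.counts[col].to_numpy(), lengths, float(lib[col]))
    res = pd.DataFrame(out, index=expr.counts.index)
    res.columns = expr.counts.columns
    return res


def paired_loading_test(l_matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided one-sample t-test of mean L against 0, per feature row,
    with BH step-up across features.

    Rows with zero variance are defined as p = 1 when the mean is 0 (no
    signal, no spread) and p = 0 otherwise.  Requires >= 2 samples.
    """
    arr = np.asarray(l_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("paired test needs an (features x >=2 samples) array")
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(arr.shape[1]))
    p = 2.0 * stats.t.sf(np.abs(t), df=arr.shape[1] - 1)
    degenerate = sd == 0
    p[degenerate & (mean == 0)] = 1.0
    p[degenerate & (mean != 0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def loading_table(
    expr: ExpressionMatrix,
    size: pd.Series | None = None,
    pseudo_fpkm: float = 1.0,
    cytosol: str = "CYTOSOL",
    polysome: str = "POLYSOME",
) -> pd.DataFrame:
    """Per-feature polysome/cytosol log2 fold changes with test results.

    Columns: feature_id, gene_id, rna_class, one ``L_<sample>`` per sample,
    mean_L, p, q.
    """
    fk = fpkm_matrix(expr, size)
    samples = expr.samples
    for s in samples:
        for fr in (cytosol, polysome):
            if (s, fr) not in fk.columns:
                raise ValueError(f"missing matched column ({s}, {fr})")
    l_cols = {}
    for s in samples:
        l_cols[f"L_{s}"] = np.log2(
            (fk[(s, polysome)].to_numpy() + pseudo_fpkm)
            / (fk[(s, cytosol)].to_numpy() + pseudo_fpkm)
        )
    out = pd.DataFrame(l_cols, index=fk.index)
    mean_l = out.to_numpy().mean(axis=1)
    if len(samples) >= 2:
        p, q = paired_loading_test(out.to_numpy())
    else:
        p = np.full(len(out), np.nan)
        q = np.full(len(out), np.nan)
    out.insert(0, "gene_id", expr.features["gene_id"])
    out.insert(1, "rna_class", expr.features["rna_class"])
    out["mean_L"] = mean_l
    out["p"] = p
    out["q"] = q
    return out.reset_index()


def class_composition(
    expr: ExpressionMatrix, size: pd.Series | None = None
) -> pd.DataFrame:
    """Percentage of summed FPKM per RNA class, per (sample, fraction).

    All-zero columns are skipped.  Returns a long table with columns
    sample_id, fraction, rna_class, percent; percentages sum to 100 per
    library.
    """
    fk = fpkm_matrix(expr, size)
    classes = expr.features["rna_class"]
    rows = []
    for col in fk.columns:
        total = fk[col].sum()
        if total == 0:
            continue
        per_class = fk[col].groupby(classes, sort=True).sum()
        for cls, v in per_class.items():
            rows.append(
                {
                    "sample_id": col[0],
                    "fraction": col[1],
                    "rna_class": cls,
                    "percent": 100.0 * v / total,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "fraction", "rna_class", "percent"])


def compare_ratio_distributions(
    ratios_a, ratios_b, n_bins: int = 20, min_expected: float = 5.0
) -> tuple[float, int, float]:
    """Chi-squared homogeneity test of two log2 loading-ratio distributions.

    Both vectors are binned on shared equal-width bins over the pooled
    range; adjacent bins are merged left to right until every expected count
    (under pooled proportions) is at least ``min_expected``.  Returns
    (chi2, df, p) with df = merged bins - 1; raises ``ValueError`` when
    fewer than 2 merged bins remain.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both ratio vectors must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ratio vectors must be finite")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        raise ValueError("degenerate pooled range; test undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)

    # Merge adjacent bins until the smaller group's expected count >= min_expected.
    n_min = min(a.size, b.size)
    total = pooled.size
    merged_a, merged_b = [], []
    acc_a = acc_b = 0
    for xa, xb in zip(ca, cb):
        acc_a += int(xa)
        acc_b += int(xb)
        if n_min * (acc_a + acc_b) / total >= min_expected:
            merged_a.append(acc_a)
            merged_b.append(acc_b)
            acc_a = acc_b = 0
    if acc_a or acc_b:
        if merged_a:
            merged_a[-1] += acc_a
            merged_b[-1] += acc_b
        else:
            merged_a, merged_b = [acc_a], [acc_b]
    if len(merged_a) < 2:
        raise ValueError("fewer than 2 merged bins; test undefined")
    table = np.array([merged_a, merged_b])
    if np.array_equal(table[0] * b.size, table[1] * a.size):
        # Identical binned distributions: chi2 exactly 0.
        return 0.0, table.shape[1] - 1, 1.0
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
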