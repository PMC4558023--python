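"""Renyi-divergence similarity of count profiles, with multinomial
bootstrap confidence intervals and hierarchical clustering.

The Renyi divergence of order alpha between probability vectors p and q is

    D_alpha(p || q) = 1/(alpha - 1) * ln sum_i p_i^alpha * q_i^(1 - alpha)

in natural-log units (nats), summing over categories where both p_i and q_i
are positive.  It generalizes the Kullback-Leibler divergence (the
alpha -> 1 limit); at alpha = 1/2 it is symmetric in its arguments and
finite whenever the supports overlap.  Sample profiles are compared on
maximum-likelihood proportions (counts / total); sampling uncertainty comes
from the non-parametric multinomial bootstrap, resampling each profile at
its observed total.  Pairwise divergence matrices feed agglomerative
clustering (UPGMA by default) with Newick export.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

__all__ = [
    "renyi_divergence",
    "kl_divergence",
    "divergence_matrix",
    "multinomial_bootstrap_ci",
    "cluster_dendrogram",
]


def _check_prob(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D probability vector")
    if (arr < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum()!r})")
    return arr


def renyi_divergence(p, q, alpha: float) -> float:
    """Renyi divergence D_alpha(p || q) in nats.

    Requires alpha > 0, alpha != 1 (use :func:`kl_divergence` for the
    alpha -> 1 limit).  Returns +inf when the joint support is empty, or
    when alpha > 1 and some category has p_i > 0 but q_i = 0.
    """
    if alpha <= 0 or alpha == 1:
        raise ValueError("alpha must be positive and != 1; use kl_divergence at alpha=1")
    p = _check_prob(p, "p")
    q = _check_prob(q, "q")
    if p.shape != q.shape:
        raise ValueError("p and q must share one category set")
    if alpha > 1 and np.any((p > 0) & (q == 0)):
        return float("inf")
    joint = (p > 0) & (q > 0)
    if not joint.any():
        return float("inf")
    s = np.sum(p[joint] ** alpha * q[joint] ** (1.0 - alpha))
    if s == 0:
        return float("inf")
    return float(np.log(s) / (alpha - 1.0))


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence sum p ln(p/q) in nats (alpha -> 1 limit)."""
    p = _check_prob(p, "p")
    q = _check_prob(q, "q")
    if np.any((p > 0) & (q == 0)):
        return float("inf")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def divergence_matrix(profiles: pd.DataFrame, alpha: float = 0.5) -> pd.DataFrame:
    """Pairwise Renyi divergences between sample count-profiles.

    ``profiles`` is categories x samples (non-negative integer counts; the
    union of categories with absent = 0).  Each column is normalized to its
    maximum-likelihood proportions.  Returns a samples x samples DataFrame
    with a zero diagonal; at alpha = 0.5 the matrix is symmetric.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two profiles")
    totals = profiles.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"profile {zero.index[0]!r} has zero total count")
    props = profiles.to_numpy(dtype=float) / totals.to_numpy(dtype=float)
    names = list(profiles.columns)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = renyi_divergence(props[:, i], props[:, j], alpha)
    return pd.DataFrame(out, index=names, columns=names)


def multinomial_bootstrap_ci(
    counts_p,
    counts_q,
    alpha: float = 0.5,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for D_alpha between two count profiles.

    Both profiles are resampled ``n_boot`` times from Multinomial(N, p_hat)
    at their observed totals; the divergence is recomputed per replicate
    (infinite replicates are retained and simply sort to the top).  Returns
    (point estimate, lower, upper) at the given level.  The percentile
    interval is widened to include the point estimate, so the lower bound
    of two identical profiles is exactly 0 (every bootstrap replicate of a
    divergence is positive, but the observed value is not).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cp = np.asarray(counts_p, dtype=np.int64)
    cq = np.asarray(counts_q, dtype=np.int64)
    n_p, n_q = int(cp.sum()), int(cq.sum())
    if n_p <= 0 or n_q <= 0:
        raise ValueError("both profiles need positive totals")
    p_hat = cp / n_p
    q_hat = cq / n_q
    point = renyi_divergence(p_hat, q_hat, alpha)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bp = rng.multinomial(n_p, p_hat, size=n_boot) / n_p
    bq = rng.multinomial(n_q, q_hat, size=n_boot) / n_q
    if alpha > 1:
        bad = ((bp > 0) & (bq == 0)).any(axis=1)
    else:
        bad = np.zeros(n_boot, dtype=bool)
    joint = (bp > 0) & (bq > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(joint, bp**alpha * bq ** (1.0 - alpha), 0.0).sum(axis=1)
        d = np.where((s > 0) & ~bad, np.log(np.maximum(s, 1e-300)) / (alpha - 1.0), np.inf)
    lo = float(np.quantile(d, (1.0 - level) / 2.0))
    hi = float(np.quantile(d, 1.0 - (1.0 - level) / 2.0))
    return point, min(lo, point), max(hi, point)


def cluster_dendrogram(
    d_matrix: pd.DataFrame,
    method: str = "average",
    inf_cap_factor: float = 1.5,
) -> tuple[np.ndarray, str]:
    """Agglomerative clustering of a divergence matrix with Newick export.

    The matrix must be symmetric (to 1e-9) with a zero diagonal; infinite
    entries are capped at ``inf_cap_factor`` times the largest finite
    off-diagonal value, since agglomerative linkage needs finite distances.
    Returns the scipy linkage matrix (merge heights = cluster distances)
    and a Newick string with branch lengths.
    """
    if method not in ("average", "single", "complete"):
        raise ValueError("linkage must be one of average, single, complete")
    mat = d_matrix.to_numpy(dtype=float).copy()
    if mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ValueError("divergence matrix must be square with >= 2 samples")
    if np.nanmax(np.abs(np.diag(mat))) > 1e-9:
        raise ValueError("divergence matrix must have a zero diagonal")
    finite = np.isfinite(mat)
    if not np.allclose(np.where(finite, mat, 0.0), np.where(finite.T, mat.T, 0.0), atol=1e-9) or not (
        finite == finite.T
    ).all():
        raise ValueError("divergence matrix must be symmetric to 1e-9")
    off = ~np.eye(mat.shape[0], dtype=bool)
    if np.isinf(mat[off]).any():
        finite_vals = mat[off & np.isfinite(mat)]
        if finite_vals.size == 0:
            raise ValueError("all off-diagonal divergences are infinite")
        mat[np.isinf(mat)] = inf_cap_factor * finite_vals.max()
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    z = linkage(squareform(mat, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(z, [str(c) for c in d_matrix.columns])
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return z, buf.getvalue().strip()
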