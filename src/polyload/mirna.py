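"""microRNA polysome/cytosol enrichment, ranking, and target overlap.

Counts are normalized to counts-per-million within each small-RNA library
(microRNAs were sequenced as separate libraries, so CPM is taken within
the microRNA count universe of each (sample, fraction)).  Per-microRNA,
per-sample enrichment is rho = (CPM_polysome + pc)/(CPM_cytosol + pc);
consistency across samples (all rho > 1 -> ENRICHED, all rho < 1 ->
DEPLETED, otherwise MIXED) plus a geometric-mean rho drive the top-k
ranking.  Significance of cytosol-vs-polysome count differences uses the
Mann-Whitney U test, exact by enumeration for small samples with midranks
for ties, and the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "mirna_loading_ratios",
    "rank_consistent_mirnas",
    "mannwhitney_u",
    "target_set_overlap",
]


def mirna_loading_ratios(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    cytosol: str = "CYTOSOL",
    polysome: str = "POLYSOME",
    test: bool = True,
) -> pd.DataFrame:
    """Per-microRNA polysome/cytosol CPM ratios with consistency calls.

    ``counts`` is mir x (sample, fraction) as read by
    :func:`polyload.formats.read_mirna_count_table`.  Returns one row per
    microRNA: mir_id, rho_<sample> per sample, geometric_mean_rho,
    consistency, U, p (Mann-Whitney on the per-sample CPM values of the two
    fractions; NaN when ``test`` is false).
    """
    samples = sorted({s for s, _ in counts.columns})
    for s in samples:
        for fr in (cytosol, polysome):
            if (s, fr) not in counts.columns:
                raise ValueError(f"missing matched microRNA profile ({s}, {fr})")
    cpm = counts / counts.sum(axis=0) * 1.0e6
    rho = pd.DataFrame(index=counts.index)
    for s in samples:
        rho[f"rho_{s}"] = (cpm[(s, polysome)] + pseudocount) / (
            cpm[(s, cytosol)] + pseudocount
        )
    arr = rho.to_numpy()
    geo = np.exp(np.mean(np.log(arr), axis=1))
    consistency = np.where(
        (arr > 1).all(axis=1), "ENRICHED", np.where((arr < 1).all(axis=1), "DEPLETED", "MIXED")
    )
    out = rho.copy()
    out["geometric_mean_rho"] = geo
    out["consistency"] = consistency
    if test:
        stats_rows = [
            mannwhitney_u(
                [cpm.loc[m, (s, cytosol)] for s in samples],
                [cpm.loc[m, (s, polysome)] for s in samples],
            )
            for m in counts.index
        ]
        out["U"] = [u for u, _ in stats_rows]
        out["p"] = [p for _, p in stats_rows]
    else:
        out["U"] = np.nan
        out["p"] = np.nan
    return out.reset_index().rename(columns={"index": "mir_id"})


def rank_consistent_mirnas(
    enrichment: pd.DataFrame, k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k consistently enriched and consistently depleted microRNAs.

    ENRICHED microRNAs are ranked by descending geometric-mean rho,
    DEPLETED by ascending; MIXED microRNAs appear in neither list.  Ties
    break lexicographically on mir_id.
    """
    enr = enrichment[enrichment["consistency"] == "ENRICHED"].sort_values(
        ["geometric_mean_rho", "mir_id"], ascending=[False, True], kind="mergesort"
    )
    dep = enrichment[enrichment["consistency"] == "DEPLETED"].sort_values(
        ["geometric_mean_rho", "mir_id"], ascending=[True, True], kind="mergesort"
    )
    return enr.head(k).reset_index(drop=True), dep.head(k).reset_index(drop=True)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with midrank handling of ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mannwhitney_u(x, y, exact_limit: int = 16) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples, two-sided.

    For n + m <= ``exact_limit`` the p-value is exact, enumerating all
    C(n+m, n) assignments of the pooled observations (midranks for ties):
    p = min(1, 2 * min(P(U <= u), P(U >= u))).  Larger samples use the
    normal approximation with tie correction and continuity correction.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])

    if n + m <= exact_limit:
        idx = range(n + m)
        total = comb(n + m, n)
        le = ge = 0
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return u_obs, p

    mu = n * m / 2.0
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0)))
    return u_obs, min(1.0, p)


def target_set_overlap(
    target_map: dict[str, set[str]], enriched_genes: set[str]
) -> tuple[pd.DataFrame, int]:
    """Overlap of each microRNA's target set with a polysome-enriched gene set.

    Returns a per-microRNA table (mir_id, n_targets, n_overlap) and the
    pooled count of unique genes in the union of the intersections.
    """
    rows = []
    pooled: set[str] = set()
    for mir in sorted(target_map):
        targets = set(target_map[mir])
        inter = targets & enriched_genes
        pooled |= inter
        rows.append({"mir_id": mir, "n_targets": len(targets), "n_overlap": len(inter)})
    return pd.DataFrame(rows, columns=["mir_id", "n_targets", "n_overlap"]), len(pooled)
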