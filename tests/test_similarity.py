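import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from polyload.similarity import (
    cluster_dendrogram,
    divergence_matrix,
    kl_divergence,
    multinomial_bootstrap_ci,
    renyi_divergence,
)


def brute_force_renyi(p, q, alpha):
    """Independent direct-summation oracle (scalar loop, no shortcuts)."""
    total = 0.0
    saw_support = False
    for pi, qi in zip(p, q):
        if pi > 0 and qi == 0 and alpha > 1:
            return float("inf")
        if pi > 0 and qi > 0:
            saw_support = True
            total += pi**alpha * qi ** (1.0 - alpha)
    if not saw_support or total == 0:
        return float("inf")
    return np.log(total) / (alpha - 1.0)


def random_distributions(rng, n_pairs, k=10):
    for _ in range(n_pairs):
        yield rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))


class TestRenyiDivergence:
    def test_identity_is_zero(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(8))
            for alpha in (0.25, 0.5, 2.0):
                assert renyi_divergence(p, p, alpha) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (0.5, -2 * np.log(np.sqrt(0.45) + np.sqrt(0.05))),  # ~0.22314
            (2.0, np.log(0.25 / 0.9 + 0.25 / 0.1)),             # ~1.02165
        ],
    )
    def test_hand_values(self, alpha, expected):
        d = renyi_divergence([0.5, 0.5], [0.9, 0.1], alpha)
        assert d == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for p, q in random_distributions(rng, 100):
            for alpha in (0.25, 0.5, 2.0):
                d = renyi_divergence(p, q, alpha)
                assert d == pytest.approx(brute_force_renyi(p, q, alpha), rel=1e-12)

    def test_alpha_to_one_limit_is_kl(self, rng):
        for p, q in random_distributions(rng, 20):
            kl = kl_divergence(p, q)
            for eps in (1e-6, -1e-6):
                assert renyi_divergence(p, q, 1 + eps) == pytest.approx(kl, abs=1e-4)

    def test_non_negative(self, rng):
        for p, q in random_distributions(rng, 50):
            assert renyi_divergence(p, q, 0.5) >= -1e-12

    def test_disjoint_support_infinite(self):
        assert renyi_divergence([1.0, 0.0], [0.0, 1.0], 0.5) == np.inf
        assert renyi_divergence([0.6, 0.4], [1.0, 0.0], 2.0) == np.inf

    def test_alpha_domain_errors(self):
        with pytest.raises(ValueError):
            renyi_divergence([1.0], [1.0], 1.0)
        with pytest.raises(ValueError):
            renyi_divergence([1.0], [1.0], -0.5)


class TestDivergenceMatrix:
    def test_identical_profiles_all_zero(self):
        prof = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30], "c": [10, 20, 30]})
        dm = divergence_matrix(prof)
        np.testing.assert_allclose(dm, 0.0, atol=1e-12)

    def test_symmetric_at_half(self, rng):
        prof = pd.DataFrame(rng.integers(1, 200, (12, 4)), columns=list("abcd"))
        dm = divergence_matrix(prof, alpha=0.5)
        np.testing.assert_allclose(dm, dm.T)

    def test_counts_match_proportion_oracle(self):
        prof = pd.DataFrame({"a": [45, 5], "b": [25, 25]})
        dm = divergence_matrix(prof, alpha=0.5)
        assert dm.loc["a", "b"] == pytest.approx(
            renyi_divergence([0.9, 0.1], [0.5, 0.5], 0.5)
        )

    def test_zero_total_profile_named(self):
        prof = pd.DataFrame({"a": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            divergence_matrix(prof)


class TestBootstrapCi:
    def test_identical_profiles_zero_lower_bound(self):
        c = np.array([50, 30, 20])
        point, lo, hi = multinomial_bootstrap_ci(c, c, seed=3)
        assert point == pytest.approx(0.0)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi >= lo

    def test_same_seed_identical(self):
        a, b = np.array([40, 30, 30]), np.array([10, 50, 40])
        r1 = multinomial_bootstrap_ci(a, b, seed=11)
        r2 = multinomial_bootstrap_ci(a, b, seed=11)
        assert r1 == r2

    def test_interval_brackets_point_for_moderate_counts(self, rng):
        a = rng.integers(20, 100, 8)
        b = rng.integers(20, 100, 8)
        point, lo, hi = multinomial_bootstrap_ci(a, b, n_boot=500, seed=5)
        assert lo <= hi
        assert lo >= 0


class TestClusterDendrogram:
    def test_all_zero_matrix_merges_at_zero(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        z, nwk = cluster_dendrogram(d)
        np.testing.assert_allclose(z[:, 2], 0.0)
        assert set("abc") == {t.name for t in TreeNode.read([nwk]).tips()}

    def test_two_clade_upgma_hand_example(self):
        names = ["s1", "s2", "s3", "s4"]
        mat = np.full((4, 4), 1.0)
        np.fill_diagonal(mat, 0.0)
        mat[0, 1] = mat[1, 0] = 0.1
        mat[2, 3] = mat[3, 2] = 0.1
        z, nwk = cluster_dendrogram(pd.DataFrame(mat, index=names, columns=names))
        np.testing.assert_allclose(sorted(z[:, 2]), [0.1, 0.1, 1.0])
        tree = TreeNode.read([nwk])
        clades = [sorted(t.name for t in c.tips()) for c in tree.children if not c.is_tip()]
        assert ["s1", "s2"] in clades or ["s3", "s4"] in clades

    def test_relabeling_preserves_heights(self, rng):
        mat = rng.random((5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        names = list("abcde")
        d1 = pd.DataFrame(mat, index=names, columns=names)
        perm = [3, 1, 4, 0, 2]
        d2 = d1.iloc[perm, perm]
        z1, _ = cluster_dendrogram(d1)
        z2, _ = cluster_dendrogram(d2)
        np.testing.assert_allclose(sorted(z1[:, 2]), sorted(z2[:, 2]))

    def test_infinities_capped(self):
        mat = np.array([[0.0, 1.0, np.inf], [1.0, 0.0, 2.0], [np.inf, 2.0, 0.0]])
        d = pd.DataFrame(mat, index=list("abc"), columns=list("abc"))
        z, _ = cluster_dendrogram(d)
        assert np.isfinite(z[:, 2]).all()
        assert z[:, 2].max() <= 1.5 * 2.0 + 1e-9

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_dendrogram(pd.DataFrame(mat, index=list("ab"), columns=list("ab")))


class TestSimulationLevelClaim:
    def test_polysome_profiles_tighter_than_cytosol(self, small_dataset):
        """Polysomal expression profiles share a loading template, so mean
        within-polysome divergence is below mean within-cytosol divergence."""
        counts = small_dataset.expression.counts
        dm = divergence_matrix(counts, alpha=0.5)
        cols = list(counts.columns)
        poly = [c for c in cols if c[1] == "POLYSOME"]
        cyt = [c for c in cols if c[1] == "CYTOSOL"]
        wp = np.mean([dm.loc[[a], [b]].iloc[0, 0] for a, b in itertools.combinations(poly, 2)])
        wc = np.mean([dm.loc[[a], [b]].iloc[0, 0] for a, b in itertools.combinations(cyt, 2)])
        assert wp < wc
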