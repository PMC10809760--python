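"""Dissimilarities, ordination identities, permutation tests, Ward ordering."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from redoxlag.ordination_stats import (
    bray_curtis,
    hellinger,
    pairwise_permanova,
    pca,
    pcoa,
    permanova,
    ward_order,
    welch_t,
)
from redoxlag.tables_io import ValidationError


def _df(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(_df([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(_df([[1, 1, 0], [0, 0, 2]]))
        assert d.iloc[0, 1] == 1.0

    def test_hand_arithmetic(self):
        d = bray_curtis(_df([[1, 1, 0], [0, 1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_double_zero_pair_defined_as_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            d = bray_curtis(_df([[0, 0], [0, 0], [1, 1]]))
        assert d.iloc[0, 1] == 0.0
        assert "all-zero" in caplog.text

    def test_bounded_and_symmetric(self, rng):
        d = bray_curtis(_df(rng.gamma(1, 1, (10, 6))))
        m = d.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all((m >= 0) & (m <= 1))
        assert np.allclose(np.diag(m), 0)


class TestHellinger:
    def test_point_mass(self):
        h = hellinger(_df([[1, 0, 0]]))
        assert h.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_uniform_row(self):
        h = hellinger(_df([[1, 1, 1, 1]]))
        assert np.allclose(h.iloc[0], 0.5)

    def test_unit_sum_of_squares(self, rng):
        h = hellinger(_df(rng.gamma(1, 1, (8, 5)) + 0.01))
        assert np.allclose((h**2).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_names_sample(self):
        with pytest.raises(ValidationError, match="s1"):
            hellinger(_df([[1, 2], [0, 0]]))

    def test_euclidean_of_hellinger_is_hellinger_distance(self, rng):
        """||h_s - h_t|| equals the Hellinger distance on raw compositions."""
        x = rng.gamma(2, 1, (6, 4)) + 0.01
        h = hellinger(_df(x)).to_numpy()
        p = x / x.sum(axis=1, keepdims=True)
        for i in range(6):
            for j in range(6):
                direct = math.sqrt(np.sum((np.sqrt(p[i]) - np.sqrt(p[j])) ** 2))
                assert np.linalg.norm(h[i] - h[j]) == pytest.approx(direct, abs=1e-12)


class TestPcoa:
    def test_classical_scaling_identity(self, rng):
        """PCoA of Euclidean distances reproduces the pairwise distances."""
        pts = rng.normal(size=(5, 3))
        from scipy.spatial.distance import pdist, squareform

        d = _df(squareform(pdist(pts)))
        d.columns = d.index
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        rebuilt = squareform(pdist(coords))
        assert np.allclose(rebuilt, d.to_numpy(), atol=1e-9)

    def test_matches_reference_implementation(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        x = rng.gamma(1, 1, (8, 5))
        d = bray_curtis(_df(x))
        mine = pcoa(d)
        ref = skbio_ordination.pcoa(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        n_pos = (mine.eigenvalues > 1e-10).sum()
        assert np.allclose(
            mine.eigenvalues.to_numpy()[:n_pos],
            ref.eigvals.to_numpy()[:n_pos],
            atol=1e-8,
        )
        assert np.allclose(
            np.abs(mine.coordinates.to_numpy()[:, :2]),
            np.abs(ref.samples.to_numpy()[:, :2]),
            atol=1e-8,
        )

    def test_negative_eigenvalues_reported(self, rng):
        x = rng.gamma(1, 1, (8, 3))
        d = bray_curtis(_df(x))  # Bray-Curtis is generally non-Euclidean
        res = pcoa(d)
        assert len(res.eigenvalues) == 8
        assert (res.eigenvalues < -1e-12).any()
        assert pcoa(d, correction="cailliez").eigenvalues.min() >= -1e-8

    def test_rejects_asymmetric(self):
        d = _df([[0, 1], [2, 0]])
        d.columns = d.index
        with pytest.raises(ValidationError, match="symmetric"):
            pcoa(d)


class TestPca:
    def test_rank_one_single_eigenvalue(self):
        x = _df(np.outer([1, 2, 3, 4], [1, 0.5]))
        res = pca(x)
        ev = res.eigenvalues.to_numpy()
        assert ev[0] > 1e-10
        assert np.all(np.abs(ev[1:]) < 1e-10)

    def test_coordinates_centered(self, rng):
        res = pca(_df(rng.normal(size=(10, 4))))
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)
        assert np.all(np.diff(res.eigenvalues.to_numpy()) <= 1e-12)

    def test_matches_sklearn(self, rng):
        decomposition = pytest.importorskip("sklearn.decomposition")
        x = rng.normal(size=(12, 5))
        mine = pca(_df(x))
        ref = decomposition.PCA(n_components=5).fit(x)
        assert np.allclose(mine.eigenvalues, ref.explained_variance_, atol=1e-10)
        assert np.allclose(
            np.abs(mine.coordinates.to_numpy()), np.abs(ref.transform(x)), atol=1e-8
        )


class TestPermanova:
    def _clouds(self, rng, sep=0.0, n=10, p=4):
        a = rng.normal(size=(n, p)) + 5
        b = rng.normal(size=(n, p)) + 5 + sep
        x = np.abs(np.vstack([a, b]))
        return _df(x), np.array(["a"] * n + ["b"] * n)

    def test_separated_clouds_minimal_p(self, rng):
        x, groups = self._clouds(rng, sep=100.0)
        d = bray_curtis(x)
        _, p = permanova(d, groups, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_deterministic_under_seed(self, rng):
        x, groups = self._clouds(rng, sep=0.5)
        d = bray_curtis(x)
        r1 = permanova(d, groups, n_perm=199, seed=42)
        r2 = permanova(d, groups, n_perm=199, seed=42)
        assert r1 == r2

    def test_statistic_matches_reference_implementation(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        x, groups = self._clouds(rng, sep=1.0)
        d = bray_curtis(x)
        f_mine, _ = permanova(d, groups, n_perm=99, seed=0)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=list(groups),
            permutations=9,
        )
        assert f_mine == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_small_group_rejected(self):
        d = bray_curtis(_df([[1, 0], [0, 1], [1, 1]]))
        with pytest.raises(ValidationError, match="fewer than 2"):
            permanova(d, ["a", "a", "b"], n_perm=99, seed=0)

    def test_pairwise_with_bh_adjustment(self, rng):
        x = np.abs(rng.normal(size=(18, 4))) + 0.1
        x[6:12] += 3.0
        x[12:] += 6.0
        groups = np.repeat(["a", "b", "c"], 6)
        d = bray_curtis(_df(x))
        table = pairwise_permanova(d, groups, n_perm=199, seed=3)
        assert len(table) == 3
        # Benjamini-Hochberg recomputed independently
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        assert np.allclose(table["p_adjusted"].to_numpy(), adj, atol=1e-12)
        table2 = pairwise_permanova(d, groups, n_perm=199, seed=3)
        assert table.equals(table2)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_clear_separation(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert p < 0.01

    def test_against_hand_computed_statistic(self):
        """Welch t and Welch-Satterthwaite df recomputed from the formulas."""
        a = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        b = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_needs_two_per_sample(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


def _ward_oracle_merges(x: np.ndarray) -> list[frozenset[int]]:
    """Naive Ward agglomeration: repeatedly merge the pair with the smallest
    SSE increase (|A||B|/(|A|+|B|) * ||mean_A - mean_B||^2)."""
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(x))}
    merges = []
    next_id = len(x)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                a, b = clusters[i], clusters[j]
                ma, mb = x[a].mean(axis=0), x[b].mean(axis=0)
                cost = len(a) * len(b) / (len(a) + len(b)) * np.sum((ma - mb) ** 2)
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        _, i, j = best
        merged = clusters.pop(i) + clusters.pop(j)
        merges.append(frozenset(merged))
        clusters[next_id] = merged
        next_id += 1
    return merges


class TestWardOrder:
    def test_identical_profiles_merge_first(self):
        x = _df([[1, 1], [5, 5], [1, 1]], prefix="g")
        order = ward_order(x)
        i0, i2 = order.index("g0"), order.index("g2")
        assert abs(i0 - i2) == 1  # twins are adjacent leaves

    def test_distant_group_is_last_merge(self):
        x = _df([[0, 0], [0.1, 0], [100, 100]], prefix="g")
        order = ward_order(x)
        assert order[0] == "g2" or order[-1] == "g2"

    def test_merge_tree_matches_brute_force_oracle(self, rng):
        from scipy.cluster import hierarchy

        x = rng.normal(size=(8, 5))
        oracle = _ward_oracle_merges(x)
        z = hierarchy.linkage(x, method="ward")
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(8)}
        scipy_merges = []
        for k, (a, b, _dist, _n) in enumerate(z):
            merged = members[int(a)] | members[int(b)]
            members[8 + k] = merged
            scipy_merges.append(merged)
        assert scipy_merges == oracle
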