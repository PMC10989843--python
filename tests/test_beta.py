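"""Ordination and permutation statistics: PCoA, PERMANOVA, dispersion,
paired divergence regression and Mantel."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from seasonet.beta import (
    beta_dispersion,
    mantel,
    paired_divergence_curve,
    pcoa,
    permanova,
)
from seasonet.core import CommunityDistance, community_distance
from seasonet.simulate import generate_design

from conftest import make_table


def euclid_dist(points: np.ndarray, scale: float = 1.0) -> CommunityDistance:
    d = squareform(pdist(points)) * scale
    ids = [f"S{i}" for i in range(len(points))]
    return CommunityDistance(ids, d / max(d.max(), 1e-12), "euclidean")


class TestPcoa:
    def test_line_recovery(self):
        pts = np.array([[0.0], [1.0], [2.0], [3.0]])
        res = pcoa(euclid_dist(pts))
        # axis 1 reproduces the line up to sign/offset
        ax1 = res.coordinates[:, 0]
        r = np.corrcoef(ax1, pts[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)

    def test_identical_samples_identical_coords(self):
        d = community_distance(make_table([[4, 4, 1], [1, 1, 5]]))
        res = pcoa(d)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_distance_reconstruction_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.random((7, 3))
        d = euclid_dist(pts)
        res = pcoa(d)
        assert res.neg_coordinates.shape[1] == 0  # Euclidean input
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, d.values, atol=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 0.5], [0.4, 0.0]]))


def _oneway_permanova_f_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's one-way pseudo-F from explicit group sums of squared
    distances (independent of the projection-matrix route)."""
    n = len(labels)
    iu = np.triu_indices(n, 1)
    ss_total = (d[iu] ** 2).sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = len(groups) - 1, n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    def test_f_matches_explicit_group_sums_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(200, rng.dirichlet(np.ones(15)), size=6).T
        table = make_table(counts)
        d = community_distance(table)
        meta = pd.DataFrame({"g": ["a", "a", "a", "b", "b", "b"]},
                            index=table.sample_ids)
        res = permanova(d, meta, terms=("g",), n_perm=99, seed=0)[0]
        oracle = _oneway_permanova_f_oracle(d.values, meta["g"].to_numpy())
        assert res.observed == pytest.approx(oracle, rel=1e-10)

    def test_study_design_degrees_of_freedom(self):
        # 2 treatments x 4 blocks x 12 months: df 1 / 11 / 11 / 3, residual 69
        meta = generate_design(4, 12)
        rng = np.random.default_rng(2)
        pts = rng.random((96, 5))
        d = CommunityDistance(list(meta.index),
                              squareform(pdist(pts)) / 10, "synthetic")
        res = permanova(d, meta, n_perm=99, seed=0)
        dfs = {r.statistic_name: r.df for r in res}
        assert dfs["pseudo-F[treatment]"] == 1
        assert dfs["pseudo-F[month]"] == 11
        assert dfs["pseudo-F[treatment:month]"] == 11
        assert dfs["pseudo-F[block]"] == 3
        assert dfs["residual"] == 69

    def test_r_squared_sums_to_one(self, small_study):
        table, meta, *_ = small_study
        d = community_distance(table)
        res = permanova(d, meta, n_perm=99, seed=0)
        assert sum(r.r_squared for r in res) == pytest.approx(1.0, abs=1e-9)

    def test_sample_order_invariance(self, small_study):
        table, meta, *_ = small_study
        d = community_distance(table)
        res1 = permanova(d, meta, n_perm=99, seed=3)
        perm_ids = list(np.random.default_rng(0).permutation(d.sample_ids))
        res2 = permanova(d.submatrix(perm_ids), meta, n_perm=99, seed=3)
        for r1, r2 in zip(res1, res2):
            assert r1.observed == pytest.approx(r2.observed, rel=1e-9) or (
                np.isnan(r1.observed) and np.isnan(r2.observed)
            )

    def test_single_level_term_rejected(self):
        meta = pd.DataFrame({"g": ["a", "a", "a", "a"]},
                            index=["S0", "S1", "S2", "S3"])
        d = euclid_dist(np.random.default_rng(0).random((4, 2)))
        with pytest.raises(ValueError):
            permanova(d, meta, terms=("g",), n_perm=99)


class TestBetaDispersion:
    def test_degenerate_group_zero_dispersion(self):
        # group a: identical samples -> zero distance to centroid
        counts = np.array([[5, 5, 5, 1, 9], [1, 1, 1, 8, 2], [3, 3, 3, 0, 7]])
        table = make_table(counts)
        d = community_distance(table)
        grouping = pd.Series(["a", "a", "a", "b", "b"], index=table.sample_ids)
        _, z = beta_dispersion(d, grouping, n_perm=99, seed=0)
        assert np.allclose(z[["S1", "S2", "S3"]], 0.0, atol=1e-9)

    def test_size_one_group_excluded(self):
        rng = np.random.default_rng(4)
        d = euclid_dist(rng.random((7, 3)))
        grouping = pd.Series(["a", "a", "a", "b", "b", "b", "c"],
                             index=d.sample_ids)
        with pytest.warns(UserWarning, match="c"):
            res, z = beta_dispersion(d, grouping, n_perm=99, seed=0)
        assert len(z) == 6

    def test_detects_unequal_dispersion(self):
        rng = np.random.default_rng(5)
        tight = rng.normal(0, 0.05, (10, 3))
        loose = rng.normal(0, 1.0, (10, 3))
        d = euclid_dist(np.vstack([tight, loose]))
        grouping = pd.Series(["a"] * 10 + ["b"] * 10, index=d.sample_ids)
        res, _ = beta_dispersion(d, grouping, n_perm=199, seed=0)
        assert res.p_value < 0.05


class TestPairedDivergence:
    @staticmethod
    def _dist_from_pairs(meta, values):
        ids = list(meta.index)
        d = np.zeros((len(ids), len(ids)))
        for (block, month), v in values.items():
            w = meta.index[(meta["block"] == block) & (meta["month"] == month)
                           & (meta["treatment"] == "warming")][0]
            c = meta.index[(meta["block"] == block) & (meta["month"] == month)
                           & (meta["treatment"] == "control")][0]
            i, j = ids.index(w), ids.index(c)
            d[i, j] = d[j, i] = v
        return CommunityDistance(ids, d, "synthetic")

    def test_exact_parabola_r2_one(self):
        meta = generate_design(1, 12)
        vals = {(1, m): 0.2 + 0.05 * m - 0.003 * m**2 for m in range(1, 13)}
        d = self._dist_from_pairs(meta, vals)
        pairs, fit = paired_divergence_curve(d, meta)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert fit["quadratic"] == pytest.approx(-0.003, abs=1e-9)

    def test_flat_input_zero_coefficients(self):
        meta = generate_design(2, 12)
        vals = {(b, m): 0.4 for b in (1, 2) for m in range(1, 13)}
        d = self._dist_from_pairs(meta, vals)
        _, fit = paired_divergence_curve(d, meta)
        assert fit["linear"] == pytest.approx(0.0, abs=1e-9)
        assert fit["quadratic"] == pytest.approx(0.0, abs=1e-9)
        assert fit["r_squared"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_pair_skipped_with_warning(self, small_study):
        table, meta, *_ = small_study
        d = community_distance(table)
        meta2 = meta.drop(index=meta.index[0])
        d2 = d.submatrix(list(meta2.index))
        with pytest.warns(UserWarning):
            pairs, _ = paired_divergence_curve(d2, meta2)
        assert len(pairs) == len(meta2) // 2


class TestMantel:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(6)
        d = euclid_dist(rng.random((8, 2)))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_exhaustive_enumeration_matches_brute_force(self):
        # n=5: all 120 permutations enumerated; compare to an independent
        # brute-force enumeration done right here
        rng = np.random.default_rng(7)
        a = euclid_dist(rng.random((5, 2)))
        b_mat = squareform(pdist(rng.random((5, 2))))
        b_mat /= b_mat.max()
        res = mantel(a, b_mat, n_perm=999, seed=0)
        iu = np.triu_indices(5, 1)
        va = a.values[iu]
        r_obs = np.corrcoef(va, b_mat[iu])[0, 1]
        count = 0
        for p in itertools.permutations(range(5)):
            r = np.corrcoef(va, b_mat[np.ix_(p, p)][iu])[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        assert res.n_perm == 120
        assert res.p_value == pytest.approx(count / 120)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(8)
        a = euclid_dist(rng.random((5, 2)))
        b = CommunityDistance([f"X{i}" for i in range(5)],
                              a.values, "other")
        with pytest.raises(ValueError):
            mantel(a, b)
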