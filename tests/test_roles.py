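"""Zi-Pi node roles and module eigengenes."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seasonet.core import OtuTable
from seasonet.roles import (
    Eigengene,
    eigengene_clustering,
    eigengene_env_correlation,
    module_eigengene,
    zi_pi,
)
from seasonet.topology import ModuleSet, greedy_modules

from conftest import make_table


def _modules_for(g, mapping):
    q = 0.0  # modularity value irrelevant for role computation
    return ModuleSet(assignment=mapping, modularity=q)


class TestZiPi:
    def test_all_links_inside_module_pi_zero(self, barbell):
        mods = _modules_for(barbell, {0: "A", 1: "A", 2: "A", 3: "B", 4: "B", 5: "B"})
        roles = {r.otu_id: r for r in zi_pi(barbell, mods)}
        assert roles[0].pi == 0.0
        assert roles[1].pi == 0.0

    def test_even_two_module_split_pi_half(self):
        # degree-4 node with 2 links into each of 2 modules
        g = nx.Graph([("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2"),
                      ("a1", "a2"), ("b1", "b2")])
        mods = _modules_for(g, {"x": "A", "a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        roles = {r.otu_id: r for r in zi_pi(g, mods)}
        assert roles["x"].pi == pytest.approx(0.5)

    def test_participation_bookkeeping_conserved(self, small_study):
        # sum over modules of a node's links equals its degree, every node
        from seasonet.network import prevalence_filter, similarity_matrix, threshold_network
        table, meta, *_ = small_study
        filt = prevalence_filter(table, list(meta.index))
        net = threshold_network(similarity_matrix(filt), 0.7)
        mods = greedy_modules(net)
        g = net.graph
        for role in zi_pi(net, mods):
            k_by_mod = {}
            for nb in g.neighbors(role.otu_id):
                k_by_mod[mods.module_of(nb)] = k_by_mod.get(mods.module_of(nb), 0) + 1
            assert sum(k_by_mod.values()) == g.degree(role.otu_id)
            pi_oracle = 1 - sum(
                (k / g.degree(role.otu_id)) ** 2 for k in k_by_mod.values()
            )
            assert role.pi == pytest.approx(pi_oracle, abs=1e-12)

    def test_zi_formula_oracle(self):
        # module = star of 5 + one peripheral pair: hand-check Zi of the hub
        g = nx.star_graph(5)  # node 0 is hub
        mapping = {v: "A" for v in g.nodes}
        roles = {r.otu_id: r for r in zi_pi(g, _modules_for(g, mapping))}
        k_within = np.array([5, 1, 1, 1, 1, 1])
        zi_oracle = (5 - k_within.mean()) / k_within.std()
        assert roles[0].zi == pytest.approx(zi_oracle)
        assert roles[0].category == "module_hub" if zi_oracle > 2.5 else True

    def test_single_member_module_zi_zero(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")])
        mods = _modules_for(g, {"a": "A", "b": "A", "c": "A", "d": "D"})
        roles = {r.otu_id: r for r in zi_pi(g, mods)}
        assert roles["d"].zi == 0.0

    def test_classification_thresholds(self):
        # synthetic roles straddling the Zi=2.5 / Pi=0.62 boundaries
        from seasonet.roles import _classify
        assert _classify(2.6, 0.1) == "module_hub"
        assert _classify(2.6, 0.7) == "network_hub"
        assert _classify(0.0, 0.7) == "connector"
        assert _classify(2.5, 0.62) == "peripheral"

    def test_uncovered_node_rejected(self, barbell):
        with pytest.raises(ValueError):
            zi_pi(barbell, _modules_for(barbell, {0: "A"}))


class TestModuleEigengene:
    @staticmethod
    def _table_and_modules(profiles, extra_noise=0):
        rng = np.random.default_rng(0)
        rows = [np.asarray(p) for p in profiles]
        for _ in range(extra_noise):
            rows.append(rng.integers(1, 50, len(rows[0])))
        counts = np.vstack(rows)
        table = make_table(counts)
        mapping = {f"OTU{i+1}": "M1" for i in range(len(profiles))}
        for j in range(extra_noise):
            mapping[f"OTU{len(profiles)+j+1}"] = "M2"
        return table, ModuleSet(mapping, 0.5)

    def test_rank_one_module(self):
        # members share one shape; the noise row varies the column totals so
        # member proportions are non-constant yet exactly rank-1
        base = np.array([10, 20, 40, 80, 30, 60])
        profiles = [base * m for m in (1, 2, 3, 4, 5)]
        table, mods = self._table_and_modules(profiles, extra_noise=1)
        eigs = module_eigengene(table, mods, min_size=5)
        assert len(eigs) == 1
        # members share the profile after per-OTU standardization of
        # proportions; variance explained is exactly 1
        assert eigs[0].variance_explained == pytest.approx(1.0, abs=1e-9)

    def test_min_size_follows_threshold(self):
        base = np.array([10, 20, 40, 80, 30, 60])
        profiles = [base * m for m in (1, 2, 3, 4)]  # only 4 members
        table, mods = self._table_and_modules(profiles, extra_noise=1)
        assert module_eigengene(table, mods, min_size=5) == []

    def test_variance_explained_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        profiles = [rng.integers(5, 200, 12) for _ in range(6)]
        table, mods = self._table_and_modules(profiles)
        eigs = module_eigengene(table, mods, min_size=5)
        prop = table.counts / table.counts.sum(axis=0)
        x = prop.iloc[:6].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        corr = z @ z.T / z.shape[1]
        lam = np.linalg.eigvalsh(corr)
        assert eigs[0].variance_explained == pytest.approx(
            lam.max() / lam.sum(), abs=1e-9
        )

    def test_eigengene_scores_standardized_and_sign_oriented(self):
        rng = np.random.default_rng(2)
        profiles = [rng.integers(5, 200, 10) for _ in range(7)]
        table, mods = self._table_and_modules(profiles)
        (eig,) = module_eigengene(table, mods, min_size=5)
        assert eig.scores.mean() == pytest.approx(0.0, abs=1e-9)
        assert eig.scores.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        prop = table.counts / table.counts.sum(axis=0)
        x = prop.iloc[:7].to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        assert np.corrcoef(eig.scores, z.mean(axis=0))[0, 1] > 0

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        profiles = [rng.integers(5, 200, 9) for _ in range(5)]
        table, mods = self._table_and_modules(profiles)
        (e1,) = module_eigengene(table, mods, min_size=5)
        perm = list(rng.permutation(table.sample_ids))
        (e2,) = module_eigengene(table.subset_samples(perm), mods, min_size=5)
        assert np.allclose(e1.scores.loc[perm].to_numpy(), e2.scores.to_numpy(),
                           atol=1e-9)


class TestEigengeneClustering:
    @staticmethod
    def _eig(module_id, scores):
        scores = np.asarray(scores, float)
        scores = (scores - scores.mean()) / scores.std(ddof=0)
        return Eigengene(module_id, pd.Series(
            scores, index=[f"S{i}" for i in range(len(scores))]), 1.0, False)

    def test_identical_eigengenes_merge_at_zero(self):
        a = self._eig("A", [1, 2, 3, 4, 5])
        b = self._eig("B", [1, 2, 3, 4, 5])
        c = self._eig("C", [5, 1, 4, 2, 3])
        z, ids = eigengene_clustering([a, b, c])
        assert z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_anticorrelated_pair_merge_height_two(self):
        a = self._eig("A", [1, 2, 3, 4])
        b = self._eig("B", [4, 3, 2, 1])
        z, _ = eigengene_clustering([a, b])
        assert z[0, 2] == pytest.approx(2.0, abs=1e-9)

    def test_matches_naive_average_linkage_oracle(self):
        rng = np.random.default_rng(4)
        eigs = [self._eig(f"M{i}", rng.random(8)) for i in range(4)]
        z, _ = eigengene_clustering(eigs)
        # naive agglomeration oracle
        mat = np.vstack([e.scores for e in eigs])
        d = 1 - np.corrcoef(mat)
        clusters = {i: [i] for i in range(4)}
        merges = []
        next_id = 4
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or h < best[0] - 1e-15:
                        best = (h, a, b)
            h, a, b = best
            merges.append(h)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        assert np.allclose(z[:, 2], merges, atol=1e-10)


class TestEigengeneEnvCorrelation:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(5)
        scores = rng.random(10)
        e = TestEigengeneClustering._eig("A", scores)
        env = pd.DataFrame({"self": e.scores}, index=e.scores.index)
        out = eigengene_env_correlation([e], env)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_p_value_matches_t_distribution_oracle(self):
        # build vectors with exact sample r = 0.576 at n = 12
        n, r = 12, 0.576
        e1 = np.zeros(n); e1[0], e1[1] = 1, -1
        e2 = np.zeros(n); e2[2], e2[3] = 1, -1
        e1 /= np.linalg.norm(e1); e2 /= np.linalg.norm(e2)
        x = e1
        y = r * e1 + np.sqrt(1 - r**2) * e2
        eig = Eigengene("A", pd.Series(
            (x - x.mean()) / x.std(ddof=0), index=[f"S{i}" for i in range(n)]),
            1.0, False)
        env = pd.DataFrame({"v": y}, index=eig.scores.index)
        out = eigengene_env_correlation([eig], env)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_oracle = 2 * stats.t.sf(t, n - 2)
        assert out.loc[0, "r"] == pytest.approx(r, abs=1e-9)
        assert out.loc[0, "p"] == pytest.approx(p_oracle, abs=1e-9)
        assert out.loc[0, "p"] == pytest.approx(0.050, abs=0.001)

    def test_constant_variable_reported_missing(self):
        e = TestEigengeneClustering._eig("A", np.arange(8))
        env = pd.DataFrame({"const": np.ones(8)}, index=e.scores.index)
        out = eigengene_env_correlation([e], env)
        assert np.isnan(out.loc[0, "r"])

    def test_missing_values_pairwise_dropped(self):
        rng = np.random.default_rng(6)
        e = TestEigengeneClustering._eig("A", rng.random(10))
        v = rng.random(10)
        v[3] = np.nan
        env = pd.DataFrame({"v": v}, index=e.scores.index)
        out = eigengene_env_correlation([e], env)
        assert out.loc[0, "n"] == 9
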