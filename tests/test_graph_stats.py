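import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from smoothsweep.connectivity import ConnectivityMatrix, MatrixStack, from_upper_triangle
from smoothsweep.core import SubjectRecord
from smoothsweep.graph_stats import (
    bh_fdr,
    groupwise_metric_tests,
    linkwise_permutation_tests,
    node_metrics,
    permutation_test,
)


def _floyd_warshall(adj):
    r = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(r):
        d = np.minimum(d, d[:, k][:, None] + d[k][None, :])
    return d


def _oracle_metrics(adj):
    """Brute-force: triangle counts, Floyd-Warshall distances, shortest-path
    counting for fractional betweenness."""
    r = adj.shape[0]
    deg = adj.sum(axis=1)
    clustering = np.zeros(r)
    for i in range(r):
        nbrs = np.nonzero(adj[i])[0]
        k = len(nbrs)
        if k >= 2:
            tri = sum(
                adj[a, b] for x, a in enumerate(nbrs) for b in nbrs[x + 1:]
            )
            clustering[i] = 2.0 * tri / (k * (k - 1))
    d = _floyd_warshall(adj)
    finite = np.isfinite(d) & (d > 0)
    geff = (1.0 / d[finite]).sum() / (r * (r - 1)) if r > 1 else 0.0
    local_eff = np.zeros(r)
    for i in range(r):
        nbrs = np.nonzero(adj[i])[0]
        k = len(nbrs)
        if k >= 2:
            sub = adj[np.ix_(nbrs, nbrs)]
            ds = _floyd_warshall(sub)
            fin = np.isfinite(ds) & (ds > 0)
            local_eff[i] = (1.0 / ds[fin]).sum() / (k * (k - 1))
    # number of shortest paths between every pair (BFS-layer DP)
    sigma = np.zeros((r, r))
    for s in range(r):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            preds = [u for u in range(r) if adj[u, v] and d[s, u] == d[s, v] - 1]
            sigma[s, v] = sum(sigma[s, u] for u in preds)
    betw = np.zeros(r)
    for v in range(r):
        total = 0.0
        for s in range(r):
            for t in range(s + 1, r):
                if s == v or t == v or not np.isfinite(d[s, t]):
                    continue
                if d[s, v] + d[v, t] == d[s, t] and sigma[s, t] > 0:
                    total += sigma[s, v] * sigma[v, t] / sigma[s, t]
        betw[v] = total / ((r - 1) * (r - 2) / 2.0)
    return deg.astype(float), clustering, local_eff, betw, float(geff)


class TestNodeMetrics:
    def test_complete_graph(self):
        adj = np.ones((4, 4), int) - np.eye(4, dtype=int)
        m = node_metrics(adj)
        assert np.allclose(m["clustering"], 1.0)
        assert m["global_efficiency"] == pytest.approx(1.0)
        assert np.allclose(m["betweenness"], 0.0)
        assert np.allclose(m["local_efficiency"], 1.0)

    def test_path_graph_betweenness(self):
        adj = np.zeros((3, 3), int)
        adj[0, 1] = adj[1, 0] = adj[1, 2] = adj[2, 1] = 1
        m = node_metrics(adj)
        assert m["betweenness"][1] == pytest.approx(1.0)
        assert m["degree"].tolist() == [1, 2, 1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            r = int(rng.integers(5, 11))
            adj = (from_upper_triangle((rng.random(r * (r - 1) // 2) < 0.35).astype(float), r)).astype(int)
            m = node_metrics(adj)
            deg, clu, leff, betw, geff = _oracle_metrics(adj)
            assert np.abs(m["degree"] - deg).max() < 1e-9
            assert np.abs(m["clustering"] - clu).max() < 1e-9
            assert np.abs(m["local_efficiency"] - leff).max() < 1e-9
            assert np.abs(m["betweenness"] - betw).max() < 1e-9
            assert abs(m["global_efficiency"] - geff) < 1e-9

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            node_metrics(np.full((3, 3), 0.5))

    def test_relabeling_invariance(self, rng):
        r = 9
        adj = (from_upper_triangle((rng.random(36) < 0.4).astype(float), r)).astype(int)
        perm = rng.permutation(r)
        m1 = node_metrics(adj)
        m2 = node_metrics(adj[np.ix_(perm, perm)])
        for key in ("degree", "clustering", "local_efficiency", "betweenness"):
            assert np.allclose(m1[key][perm], m2[key], atol=1e-12)


class TestPermutationTest:
    def test_exhaustive_enumeration_example(self):
        out = permutation_test([10, 11, 12], [0, 1, 2], n_perm=1000)
        assert out.exhaustive
        assert out.p_value == pytest.approx(0.1)  # 2 of 20 relabelings tie |dmean|

    def test_identical_multisets_give_p_one(self):
        out = permutation_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=500)
        assert out.p_value == pytest.approx(1.0)

    def test_monte_carlo_path_used_for_large_groups(self, rng):
        out = permutation_test(rng.standard_normal(30), rng.standard_normal(30),
                               n_perm=200, seed=1)
        assert not out.exhaustive
        assert 1 / 201 <= out.p_value <= 1.0

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        reps = 300
        for i in range(reps):
            x = rng.standard_normal(12)
            y = rng.standard_normal(12)
            if permutation_test(x, y, n_perm=200, seed=i).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestBhFdr:
    def test_step_up_example_all_rejected(self):
        mask = bh_fdr(np.array([0.01, 0.02, 0.04, 0.05]), alpha=0.05)
        assert mask.all()  # p(4) = 0.05 <= 4*0.05/4

    def test_all_ones_rejects_nothing(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_single_p_reduces_to_raw_test(self):
        assert bh_fdr(np.array([0.04]), 0.05).all()
        assert not bh_fdr(np.array([0.06]), 0.05).any()

    def test_matches_reference_step_up_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40))).clip(1e-9, 1.0)
            mine = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(mine, ref)


def _toy_stack(rng, n_per_group=8, r=10, hub_boost=0.0, link_delta=0.0):
    l = r * (r - 1) // 2
    subs, mats = [], []
    for g in ("patient", "control"):
        for i in range(n_per_group):
            vec = rng.standard_normal(l) * 0.2 + 0.1
            w = from_upper_triangle(np.tanh(vec), r)
            if g == "patient":
                if hub_boost:
                    w[0, 1:] += hub_boost
                    w[1:, 0] += hub_boost
                if link_delta:
                    w[0, 1] += link_delta
                    w[1, 0] += link_delta
            w = np.clip(w, -0.99, 0.99)
            subs.append(SubjectRecord(id=f"{g}{i}", group=g))
            mats.append(ConnectivityMatrix(w))
    return MatrixStack(subs, mats)


class TestGroupwiseTests:
    def test_deterministic_given_seed(self, rng):
        stack = _toy_stack(rng)
        a = groupwise_metric_tests(stack, density=0.2, n_perm=100, seed=4)
        b = groupwise_metric_tests(stack, density=0.2, n_perm=100, seed=4)
        for k in a:
            assert a[k].equals(b[k])

    def test_planted_hub_degree_detected(self, rng):
        hits = 0
        for i in range(10):
            stack = _toy_stack(rng, hub_boost=0.8)
            tables = groupwise_metric_tests(stack, density=0.2, n_perm=2000, seed=i)
            if tables["degree"].loc[0, "q_reject"]:
                hits += 1
        assert hits >= 8

    def test_identical_groups_yield_no_linkwise_rejections(self, rng):
        l = 45
        w = from_upper_triangle(np.tanh(rng.standard_normal(l) * 0.3), 10)
        subs = [SubjectRecord(id=f"s{i}", group="patient" if i < 4 else "control")
                for i in range(8)]
        mats = [ConnectivityMatrix(w.copy()) for _ in range(8)]
        out = linkwise_permutation_tests(MatrixStack(subs, mats), density=0.2,
                                         n_perm=100, seed=0)
        iu = np.triu_indices(10, 1)
        assert np.allclose(out["p"][iu], 1.0)
        assert not out["reject"].any()

    def test_planted_link_recovered(self, rng):
        hits = 0
        for i in range(10):
            stack = _toy_stack(rng, link_delta=0.8)
            out = linkwise_permutation_tests(stack, density=0.2, n_perm=2000, seed=i)
            if out["reject"][0, 1]:
                hits += 1
        assert hits >= 8
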