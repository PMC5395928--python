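"""Graph topology metrics against independent brute-force oracles."""

import numpy as np
import pytest

from nirsconn import connectivity as conn
from nirsconn import graph_metrics as gm
from nirsconn.connectivity import BrainGraph


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i - 1, j - 1] = a[j - 1, i - 1] = 1
    return BrainGraph(a, tuple(range(1, n + 1)))


def complete_graph(n):
    a = 1 - np.eye(n, dtype=int)
    return BrainGraph(a, tuple(range(1, n + 1)))


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive: triangle enumeration + BFS)


def bf_clustering(adj):
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(adj[u, v] for ai, u in enumerate(nbrs)
                    for v in nbrs[ai + 1:])
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def bf_distances(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier, d = [s], 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def bf_path_length(adj):
    dist = bf_distances(adj)
    finite = dist[(dist > 0) & np.isfinite(dist)]
    return float(np.mean(finite)) if finite.size else float("nan")


def bf_global_efficiency(adj):
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = bf_distances(adj)
    with np.errstate(divide="ignore"):
        inv = np.where((dist > 0) & np.isfinite(dist), 1.0 / dist, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def bf_local_efficiency(adj):
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(bf_global_efficiency(sub))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_triangle_clustering_is_one(self):
        g = graph_from_edges(3, [(1, 2), (2, 3), (1, 3)])
        assert gm.clustering_coefficient(g) == pytest.approx(1.0)

    def test_path_graph_clustering_zero(self):
        g = graph_from_edges(4, [(1, 2), (2, 3), (3, 4)])
        assert gm.clustering_coefficient(g) == pytest.approx(0.0)

    def test_kite_clustering_seven_twelfths(self):
        g = graph_from_edges(4, [(1, 2), (1, 3), (2, 3), (3, 4)])
        assert gm.clustering_coefficient(g) == pytest.approx(7 / 12)

    def test_complete_graph_all_metrics_one(self):
        g = complete_graph(4)
        m = gm.global_metrics(g)
        assert (m.cp, m.lp, m.eloc, m.eglob) == (1.0, 1.0, 1.0, 1.0)

    def test_p3_path_length_four_thirds(self):
        g = graph_from_edges(3, [(1, 2), (2, 3)])
        assert gm.characteristic_path_length(g) == pytest.approx(4 / 3)

    def test_disconnected_dyads_reachable_pairs_policy(self):
        g = graph_from_edges(4, [(1, 2), (3, 4)])
        assert gm.characteristic_path_length(g) == pytest.approx(1.0)
        assert gm.disconnected_pair_fraction(g) == pytest.approx(2 / 3)

    def test_p3_global_efficiency(self):
        g = graph_from_edges(3, [(1, 2), (2, 3)])
        assert gm.global_efficiency(g) == pytest.approx(5 / 6)

    def test_empty_graph_limits(self):
        g = graph_from_edges(4, [])
        m = gm.global_metrics(g)
        assert m.cp == 0.0 and m.eloc == 0.0 and m.eglob == 0.0
        assert np.isnan(m.lp)

    def test_star_graph_local_efficiency_zero(self):
        g = graph_from_edges(5, [(1, 2), (1, 3), (1, 4), (1, 5)])
        assert gm.local_efficiency(g) == pytest.approx(0.0)

    def test_kite_local_efficiency_matches_oracle(self):
        g = graph_from_edges(4, [(1, 2), (1, 3), (2, 3), (3, 4)])
        assert gm.local_efficiency(g) == pytest.approx(
            bf_local_efficiency(g.adjacency))


class TestOracleAgreement:
    def test_random_graphs_match_brute_force(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            p = rng.uniform(0.1, 0.9)
            a = (rng.random((n, n)) < p).astype(int)
            a = np.triu(a, 1)
            a = a + a.T
            g = BrainGraph(a, tuple(range(1, n + 1)))
            assert gm.clustering_coefficient(g) == pytest.approx(
                bf_clustering(a), abs=1e-12)
            lp, bf_lp = gm.characteristic_path_length(g), bf_path_length(a)
            if np.isnan(bf_lp):
                assert np.isnan(lp)
            else:
                assert lp == pytest.approx(bf_lp, abs=1e-12)
            assert gm.global_efficiency(g) == pytest.approx(
                bf_global_efficiency(a), abs=1e-12)
            assert gm.local_efficiency(g) == pytest.approx(
                bf_local_efficiency(a), abs=1e-12)


class TestNodalMetrics:
    def test_uniform_matrix_strengths(self):
        r = np.full((6, 6), 0.5)
        np.fill_diagonal(r, 1.0)
        mat = conn.ConnectivityMatrix(r, tuple(range(1, 7)))
        nm = gm.nodal_strength(mat)
        np.testing.assert_allclose(nm.strength, 0.5)

    def test_strength_matches_loop_oracle(self, rng):
        data = rng.normal(size=(200, 8))
        r = np.corrcoef(data, rowvar=False)
        mat = conn.ConnectivityMatrix(r, tuple(range(1, 9)))
        nm = gm.nodal_strength(mat)
        for i in range(8):
            manual = np.mean([r[i, j] for j in range(8) if j != i])
            assert nm.strength[i] == pytest.approx(manual, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        data = rng.normal(size=(200, 6))
        r = np.corrcoef(data, rowvar=False)
        perm = rng.permutation(6)
        a = gm.nodal_strength(conn.ConnectivityMatrix(r, tuple(range(1, 7))))
        b = gm.nodal_strength(conn.ConnectivityMatrix(
            r[np.ix_(perm, perm)], tuple(int(p) + 1 for p in perm)))
        np.testing.assert_allclose(b.strength, a.strength[perm], atol=1e-12)


def watts_strogatz(n=24, k=4, p=0.1, seed=0):
    import networkx as nx
    G = nx.watts_strogatz_graph(n, k, p, seed=seed)
    a = nx.to_numpy_array(G, nodelist=sorted(G)).astype(int)
    return BrainGraph(a, tuple(range(1, n + 1)))


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        g = watts_strogatz(seed=3)
        out = gm.random_rewire(g, seed=42)
        assert sorted(out.adjacency.sum(axis=0)) == sorted(
            g.adjacency.sum(axis=0))
        assert out.n_edges == g.n_edges

    def test_same_seed_reproducible(self):
        g = watts_strogatz(seed=5)
        a = gm.random_rewire(g, seed=7)
        b = gm.random_rewire(g, seed=7)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_rewiring_destroys_ring_clustering(self):
        """A rewired ring lattice loses clustering nearly always."""
        g = watts_strogatz(p=0.05, seed=1)
        base = gm.clustering_coefficient(g)
        lower = sum(
            gm.clustering_coefficient(gm.random_rewire(g, seed=s)) < base
            for s in range(30))
        assert lower >= 0.95 * 30 - 1  # allow one tie

    def test_too_few_edges_returns_input(self):
        g = graph_from_edges(3, [(1, 2)])
        with pytest.warns(UserWarning):
            out = gm.random_rewire(g, seed=0)
        assert np.array_equal(out.adjacency, g.adjacency)


class TestNormalization:
    def test_self_normalization_is_unity(self, rng):
        g = watts_strogatz(seed=9)
        m = gm.global_metrics(g)
        nm = gm.normalize_metrics(m, m)
        assert (nm.gamma, nm.lam, nm.gamma_e, nm.lambda_e, nm.sw) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_ratio_arithmetic(self):
        t = gm.GlobalMetrics(cp=0.6, lp=2.0, eloc=0.5, eglob=0.4)
        r = gm.GlobalMetrics(cp=0.4, lp=2.0, eloc=0.25, eglob=0.8)
        nm = gm.normalize_metrics(t, r)
        assert nm.gamma == pytest.approx(1.5)
        assert nm.lam == pytest.approx(1.0)
        assert nm.gamma_e == pytest.approx(2.0)
        assert nm.lambda_e == pytest.approx(0.5)
        assert nm.sw == pytest.approx(1.5)

    def test_zero_reference_gives_nan_with_warning(self):
        t = gm.GlobalMetrics(cp=0.6, lp=2.0, eloc=0.5, eglob=0.4)
        r = gm.GlobalMetrics(cp=0.0, lp=2.0, eloc=0.5, eglob=0.4)
        with pytest.warns(UserWarning):
            nm = gm.normalize_metrics(t, r)
        assert np.isnan(nm.gamma) and np.isnan(nm.sw)

    def test_watts_strogatz_small_world_vs_rewired_nulls(self):
        g = watts_strogatz(n=24, k=4, p=0.1, seed=2)
        null = gm.random_reference_metrics(g, n_rewires=50, seed=3)
        nm = gm.normalize_metrics(gm.global_metrics(g), null,
                                  mode="random_null")
        assert nm.sw > 1.0


class TestSparsitySweep:
    def _subject_mats(self, rng, n_subj, base, within):
        from nirsconn import synthetic_data as sd
        from nirsconn.montage_io import default_montage
        montage = default_montage()
        R = sd.build_coupling(montage, base, within, mirror=base)
        mats = []
        for _ in range(n_subj):
            noise = rng.normal(size=(200, 12))
            w, V = np.linalg.eigh(R)
            y = noise @ (V * np.sqrt(np.clip(w, 0, None))).T
            mats.append(conn.ConnectivityMatrix(
                np.corrcoef(y, rowvar=False), tuple(range(1, 13))))
        return mats

    def test_metrics_monotone_and_complete_limit(self, rng):
        mats = self._subject_mats(rng, 3, 0.3, 0.6)
        group = conn.group_mean_matrix(mats)
        grid = np.arange(0.05, 1.0001, 0.05)
        sweep = gm.sparsity_sweep({"HD": group, "CG": group}, grid,
                                  {"HD": mats[:2], "CG": mats[1:]})
        for g in ("HD", "CG"):
            curve = sweep.group_curves[g]
            # Eglob grows monotonically under nested edge addition; Cp does
            # not in general (a triangle gaining a pendant edge drops from
            # 1 to 7/12), so only the true invariant is asserted.
            assert np.all(np.diff(curve["eglob"]) >= -1e-12)
            last = curve.iloc[-1]
            assert (last["cp"], last["lp"], last["eloc"], last["eglob"]) == (
                1.0, 1.0, 1.0, 1.0)

    def test_planted_modular_group_has_higher_clustering(self, rng):
        """Stronger within-module coupling in one group shows up as a
        significantly higher clustering coefficient over some sparsity range
        in most replicate cohorts."""
        detected = 0
        n_rep = 10
        for _ in range(n_rep):
            strong = self._subject_mats(rng, 6, 0.15, 0.75)
            weak = self._subject_mats(rng, 6, 0.35, 0.45)
            sweep = gm.sparsity_sweep(
                {"HD": conn.group_mean_matrix(strong),
                 "CG": conn.group_mean_matrix(weak)},
                np.arange(0.05, 0.9, 0.05),
                {"HD": strong, "CG": weak})
            ranges = sweep.significant_ranges["cp"]
            if ranges:
                s0 = ranges[0][0]
                hd = sweep.subject_curves["HD"]["cp"][:, list(sweep.s_grid).index(s0)]
                cg = sweep.subject_curves["CG"]["cp"][:, list(sweep.s_grid).index(s0)]
                if hd.mean() > cg.mean():
                    detected += 1
        assert detected >= 0.8 * n_rep

    def test_empty_grid_rejected(self, rng):
        mats = self._subject_mats(rng, 2, 0.3, 0.5)
        group = conn.group_mean_matrix(mats)
        with pytest.raises(ValueError):
            gm.sparsity_sweep({"HD": group, "CG": group}, [],
                              {"HD": mats, "CG": mats})
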