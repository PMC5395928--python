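"""Graph topology of thresholded connectivity networks.

Global metrics on binary graphs: clustering coefficient Cp, characteristic
path length Lp, local efficiency Eloc, global efficiency Eglob.  Nodal
metrics: connectivity strength (mean off-diagonal correlation of a node)
and nodal efficiency.

Two small-world normalizations are supported for the ratio indices
gamma (Cp), lambda (Lp), gammaE (Eloc), lambdaE (Eglob) and the
small-worldness index sw = gamma/lambda:

* traditional -- the reference is the mean over degree-preserving random
  rewirings of the target network;
* group-referenced ("intuitive") -- the reference is the control group's
  network at the same sparsity, asking whether the target group's network
  is small-world *with respect to the controls*.

The sparsity sweep profiles all four global metrics over a grid of
sparsity thresholds, compares groups per threshold with two-sample t-tests
across subjects, and controls the sweep-wise false discovery rate by
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import BrainGraph, ConnectivityMatrix, threshold_sparsity
from .errors import NirsconnError

METRIC_NAMES = ("cp", "lp", "eloc", "eglob")


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    eloc: float
    eglob: float
    sparsity: float | None = None

    def as_dict(self):
        return {"cp": self.cp, "lp": self.lp, "eloc": self.eloc,
                "eglob": self.eglob}


@dataclass(frozen=True)
class NodalMetrics:
    node_labels: tuple
    strength: np.ndarray
    nodal_efficiency: np.ndarray


@dataclass(frozen=True)
class NormalizedMetrics:
    gamma: float
    lam: float
    gamma_e: float
    lambda_e: float
    sw: float
    reference: str

    def as_dict(self):
        return {"gamma": self.gamma, "lambda": self.lam,
                "gammaE": self.gamma_e, "lambdaE": self.lambda_e,
                "sw": self.sw, "reference": self.reference}


def _as_nx(g) -> nx.Graph:
    return g.to_networkx() if isinstance(g, BrainGraph) else g


def clustering_coefficient(g) -> float:
    """Mean local clustering; nodes of degree < 2 contribute 0."""
    G = _as_nx(g)
    if G.number_of_nodes() == 0:
        return 0.0
    return float(np.mean(list(nx.clustering(G).values())))


def characteristic_path_length(g) -> float:
    """Mean shortest-path length over reachable node pairs.

    Unreachable pairs are excluded from the average (the disconnected-pair
    policy that keeps Lp finite across the whole sparsity range); with no
    reachable pair at all the result is NaN with a warning.
    """
    G = _as_nx(g)
    total, count = 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        warnings.warn("no reachable node pairs; path length undefined")
        return float("nan")
    return total / count


def disconnected_pair_fraction(g) -> float:
    G = _as_nx(g)
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    reached = sum(len(d) - 1 for _, d in nx.all_pairs_shortest_path_length(G))
    return 1.0 - reached / (n * (n - 1))


def global_efficiency(g) -> float:
    """Mean inverse shortest-path length over all pairs (1/inf = 0)."""
    G = _as_nx(g)
    if G.number_of_nodes() < 2:
        return 0.0
    return float(nx.global_efficiency(G))


def local_efficiency(g) -> float:
    """Mean, over nodes, of the global efficiency of each neighborhood subgraph."""
    G = _as_nx(g)
    if G.number_of_nodes() == 0:
        return 0.0
    return float(nx.local_efficiency(G))


def global_metrics(g, sparsity: float | None = None) -> GlobalMetrics:
    return GlobalMetrics(cp=clustering_coefficient(g),
                         lp=characteristic_path_length(g),
                         eloc=local_efficiency(g),
                         eglob=global_efficiency(g),
                         sparsity=sparsity)


def nodal_strength(matrix: ConnectivityMatrix) -> NodalMetrics:
    """Connectivity strength and nodal efficiency per channel.

    Strength of node i is the mean of its off-diagonal row entries (the
    column mean of the correlation matrix).  Nodal efficiency is the mean
    inverse shortest-path length from the node to all others on the
    positive-correlation graph.  Masked nodes report NaN.
    """
    r = matrix.values_r
    n = matrix.n
    off = ~np.eye(n, dtype=bool)
    strength = np.array([
        np.nanmean(r[i][off[i]]) if np.isfinite(r[i][off[i]]).any() else np.nan
        for i in range(n)])
    strength[~matrix.mask] = np.nan
    pos = BrainGraph((np.nan_to_num(r) > 0).astype(int) & off.astype(int),
                     matrix.channel_labels)
    G = pos.to_networkx()
    eff = []
    for i, label in enumerate(matrix.channel_labels):
        if not matrix.mask[i]:
            eff.append(np.nan)
            continue
        dists = nx.single_source_shortest_path_length(G, label)
        inv = [1.0 / d for node, d in dists.items() if d > 0]
        eff.append(sum(inv) / (n - 1) if n > 1 else 0.0)
    return NodalMetrics(matrix.channel_labels, strength, np.asarray(eff))


def random_rewire(g: BrainGraph, n_iterations: int | None = None,
                  seed: int | None = None) -> BrainGraph:
    """Degree-preserving double-edge-swap randomization.

    Performs ``n_iterations`` swaps (default 10x the edge count).  Graphs
    admitting no swap are returned unchanged with a warning.
    """
    G = g.to_networkx()
    m = G.number_of_edges()
    if m < 2:
        warnings.warn("graph has < 2 edges; rewiring impossible")
        return BrainGraph(g.adjacency.copy(), g.node_labels,
                          sparsity=g.sparsity, cutoff=g.cutoff)
    nswap = n_iterations if n_iterations is not None else 10 * m
    try:
        nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap + 100,
                            seed=seed)
    except nx.NetworkXException as exc:
        warnings.warn(f"rewiring aborted ({exc}); returning input graph")
        return BrainGraph(g.adjacency.copy(), g.node_labels,
                          sparsity=g.sparsity, cutoff=g.cutoff)
    idx = {label: i for i, label in enumerate(g.node_labels)}
    a = np.zeros_like(g.adjacency)
    for u, v in G.edges():
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    return BrainGraph(a, g.node_labels, sparsity=g.sparsity, cutoff=g.cutoff)


def _ratio(num, den):
    if den is None or not np.isfinite(den) or den == 0:
        warnings.warn("zero or undefined reference metric; ratio set to NaN")
        return float("nan")
    if num is None or not np.isfinite(num):
        return float("nan")
    return num / den


def normalize_metrics(target: GlobalMetrics, reference: GlobalMetrics,
                      mode: str = "control_group") -> NormalizedMetrics:
    """Elementwise metric ratios target/reference and sw = gamma/lambda."""
    gamma = _ratio(target.cp, reference.cp)
    lam = _ratio(target.lp, reference.lp)
    return NormalizedMetrics(
        gamma=gamma, lam=lam,
        gamma_e=_ratio(target.eloc, reference.eloc),
        lambda_e=_ratio(target.eglob, reference.eglob),
        sw=_ratio(gamma, lam),
        reference=mode)


def random_reference_metrics(g: BrainGraph, n_rewires: int = 100,
                             seed: int = 0) -> GlobalMetrics:
    """Mean global metrics over degree-preserving rewired null graphs."""
    rng = np.random.default_rng(seed)
    acc = {k: [] for k in METRIC_NAMES}
    for _ in range(n_rewires):
        null = random_rewire(g, seed=int(rng.integers(2 ** 31 - 1)))
        m = global_metrics(null)
        for k in METRIC_NAMES:
            acc[k].append(getattr(m, k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = {k: float(np.nanmean(v)) for k, v in acc.items()}
    return GlobalMetrics(cp=means["cp"], lp=means["lp"], eloc=means["eloc"],
                         eglob=means["eglob"], sparsity=g.sparsity)


@dataclass
class SweepResult:
    """Output of the sparsity sweep."""

    s_grid: np.ndarray
    group_curves: dict        # group -> DataFrame (index S, columns metrics)
    subject_curves: dict      # group -> {metric: (subjects, S) array}
    pvalues: pd.DataFrame     # index S, columns metrics
    rejected: pd.DataFrame    # BH-FDR decisions, same shape
    significant_ranges: dict  # metric -> list of (S_lo, S_hi)


def _contiguous_ranges(s_grid, mask):
    ranges, start = [], None
    for s, flag in zip(s_grid, mask):
        if flag and start is None:
            start = s
        elif not flag and start is not None:
            ranges.append((start, prev))
            start = None
        prev = s
    if start is not None:
        ranges.append((start, s_grid[-1]))
    return ranges


def sparsity_sweep(group_matrices: dict, s_grid,
                   per_subject_matrices: dict,
                   fdr_q: float = 0.05) -> SweepResult:
    """Profile the four global metrics over a sparsity grid and compare groups.

    ``group_matrices`` maps group name to its group-level matrix;
    ``per_subject_matrices`` maps group name to the list of subject
    matrices.  Per threshold, each metric is compared across the two
    groups' subjects with a two-sample t-test; the p-value curve of each
    metric is then Benjamini-Hochberg corrected over the grid at
    ``fdr_q`` and contiguous significant sparsity ranges are reported.
    """
    from .group_stats import bh_fdr

    s_grid = np.asarray(list(s_grid), dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty sparsity grid")
    groups = list(group_matrices)

    group_curves = {}
    for g in groups:
        rows = [global_metrics(threshold_sparsity(group_matrices[g], s),
                               sparsity=s).as_dict() for s in s_grid]
        group_curves[g] = pd.DataFrame(rows, index=s_grid)

    subject_curves = {}
    for g, mats in per_subject_matrices.items():
        curves = {k: np.empty((len(mats), s_grid.size)) for k in METRIC_NAMES}
        for si, mat in enumerate(mats):
            for sj, s in enumerate(s_grid):
                m = global_metrics(threshold_sparsity(mat, s))
                for k in METRIC_NAMES:
                    curves[k][si, sj] = getattr(m, k)
        subject_curves[g] = curves

    if len(groups) != 2:
        raise NirsconnError("group comparison needs exactly two groups")
    ga, gb = groups
    pvals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in METRIC_NAMES:
            a, b = subject_curves[ga][k], subject_curves[gb][k]
            p = np.ones(s_grid.size)
            for sj in range(s_grid.size):
                x, y = a[:, sj], b[:, sj]
                x, y = x[np.isfinite(x)], y[np.isfinite(y)]
                if len(x) > 1 and len(y) > 1 and (np.std(x) > 0 or np.std(y) > 0):
                    p[sj] = stats.ttest_ind(x, y, equal_var=False).pvalue
            pvals[k] = p
    pvalues = pd.DataFrame(pvals, index=s_grid)

    rejected = {}
    ranges = {}
    for k in METRIC_NAMES:
        _, rej = bh_fdr(pvalues[k].to_numpy(), q=fdr_q)
        rejected[k] = rej
        ranges[k] = _contiguous_ranges(s_grid, rej)
    return SweepResult(s_grid=s_grid, group_curves=group_curves,
                       subject_curves=subject_curves, pvalues=pvalues,
                       rejected=pd.DataFrame(rejected, index=s_grid),
                       significant_ranges=ranges)


def normalized_curves(target_matrix: ConnectivityMatrix,
                      reference_matrix: ConnectivityMatrix, s_grid,
                      n_rewires: int = 100, seed: int = 0) -> pd.DataFrame:
    """gamma/lambda/gammaE/lambdaE/sw over sparsity, both normalizations.

    Columns are MultiIndex (mode, index) with mode in
    {"control_group", "random_null"}: the group-referenced ratios divide the
    target group's metrics by the reference group's at the same S; the
    traditional ratios divide by the mean over degree-preserving rewires of
    the target graph.
    """
    rows = {}
    rng = np.random.default_rng(seed)
    for s in np.asarray(list(s_grid), dtype=float):
        gt = threshold_sparsity(target_matrix, s)
        gr = threshold_sparsity(reference_matrix, s)
        mt = global_metrics(gt, sparsity=s)
        intuitive = normalize_metrics(mt, global_metrics(gr, sparsity=s),
                                      mode="control_group")
        null = random_reference_metrics(gt, n_rewires=n_rewires,
                                        seed=int(rng.integers(2 ** 31 - 1)))
        traditional = normalize_metrics(mt, null, mode="random_null")
        row = {}
        for mode, nm in (("control_group", intuitive),
                         ("random_null", traditional)):
            for key, val in nm.as_dict().items():
                if key != "reference":
                    row[(mode, key)] = val
        rows[s] = row
    df = pd.DataFrame(rows).T
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["mode", "index"])
    df.index.name = "sparsity"
    return df
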