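"""Correlation-based functional connectivity.

Three views of the same preprocessed cohort:

* interhemispheric correlations -- Pearson r between every channel and its
  contralateral mirror channel, aggregated per ROI family (overall, lateral
  OFC, medial OFC) for HbO and Hb separately;
* seed-based maps -- the Fisher-z row of a chosen seed channel;
* whole-brain matrices -- all pairwise Pearson correlations, Fisher
  z-transformed, averaged across subjects in z-space at group level.

Thresholding turns a group matrix into a binary graph either by an
absolute rule (r cutoff, or the top fraction of connections) or by a
relative sparsity S that keeps the round(S * N(N-1)/2) strongest positive
edges.  Ties are broken by stable channel-pair order, which makes edge
sets nested across sparsity levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NirsconnError
from .montage_io import ProbeMontage
from .preprocess import HemoTimeSeries

Z_CAP_R = 0.9999  # degenerate |r| ~ 1 edges are capped here before arctanh


def fisher_z(r):
    """Fisher transformation z = arctanh(r); domain error at |r| >= 1."""
    r = np.asarray(r, dtype=float)
    finite = np.isfinite(r)
    if np.any(np.abs(r[finite]) >= 1):
        raise ValueError("|r| >= 1 outside the Fisher transform domain")
    return np.arctanh(r)


def fisher_z_inv(z):
    """Inverse Fisher transformation r = tanh(z)."""
    return np.tanh(np.asarray(z, dtype=float))


def _guarded_z(r):
    """arctanh with |r| capped at Z_CAP_R; NaN propagates."""
    r = np.asarray(r, dtype=float)
    capped = np.clip(r, -Z_CAP_R, Z_CAP_R)
    if np.any(np.abs(r[np.isfinite(r)]) > Z_CAP_R):
        warnings.warn("correlation magnitude ~1 capped before Fisher transform")
    return np.arctanh(capped)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel-by-channel correlation matrix with validity mask."""

    values_r: np.ndarray
    channel_labels: tuple
    mask: np.ndarray = None
    level: str = "subject"
    signal: str = "HbO"
    values_z: np.ndarray = field(init=False)

    def __post_init__(self):
        r = np.asarray(self.values_r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise NirsconnError("connectivity matrix must be square")
        if self.mask is None:
            off = ~np.eye(r.shape[0], dtype=bool)
            self.mask = np.array([np.isfinite(r[i][off[i]]).any()
                                  for i in range(r.shape[0])])
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values_r = r
        with np.errstate(invalid="ignore"):
            z = _guarded_z(np.where(np.eye(r.shape[0], dtype=bool), np.nan, r))
        self.values_z = z

    @property
    def n(self) -> int:
        return self.values_r.shape[0]

    def index_of(self, label) -> int:
        return self.channel_labels.index(label)

    def off_diagonal_pairs(self):
        """Upper-triangle (i, j) index pairs in stable label order."""
        return [(i, j) for i in range(self.n) for j in range(i + 1, self.n)]


def whole_brain_matrix(series: HemoTimeSeries,
                       signal: str = "HbO") -> ConnectivityMatrix:
    """Pairwise Pearson correlation over time; masked channels become NaN."""
    data = series.signal(signal)
    valid = series.valid_channels.copy()
    if valid.sum() < 2:
        raise NirsconnError("need at least 2 valid channels")
    sd = data.std(axis=0)
    zero_var = (sd == 0) & valid
    if zero_var.any():
        warnings.warn(f"zero-variance channels masked: "
                      f"{[series.channel_ids[i] for i in np.flatnonzero(zero_var)]}")
        valid = valid & ~zero_var
    n = series.n_channels
    r = np.full((n, n), np.nan)
    idx = np.flatnonzero(valid)
    sub = np.corrcoef(data[:, idx], rowvar=False)
    r[np.ix_(idx, idx)] = sub
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    return ConnectivityMatrix(r, tuple(series.channel_ids), mask=valid,
                              level="subject", signal=signal)


@dataclass
class InterhemisphericResult:
    """Mirror-pair correlations and ROI-family aggregates for one subject."""

    pair_r: dict          # signal -> {(right, left): r}
    roi_means: dict       # signal -> {"overall": r, "lOFC": r, "mOFC": r}
    level: str = "subject"


def interhemispheric_correlation(series: HemoTimeSeries,
                                 montage: ProbeMontage) -> InterhemisphericResult:
    """Pearson r of every channel with its contralateral mirror channel.

    Pairs with a masked member are omitted from the ROI aggregates.  The
    overall mean is the mean over all mirrored pairs; ROI means use only
    that ROI family's pairs.
    """
    pair_r, roi_means = {}, {}
    for sig in ("HbO", "Hb"):
        data = series.signal(sig)
        pairs = {}
        for (cr, cl) in montage.mirror_pairs():
            i, j = montage.index_of(cr), montage.index_of(cl)
            if not (series.valid_channels[i] and series.valid_channels[j]):
                pairs[(cr, cl)] = np.nan
                continue
            pairs[(cr, cl)] = float(np.corrcoef(data[:, i], data[:, j])[0, 1])
        pair_r[sig] = pairs
        by_roi = {"overall": list(pairs.values())}
        for fam in ("lOFC", "mOFC"):
            by_roi[fam] = [v for p, v in pairs.items()
                           if montage.roi_of_pair(p) == fam]
        roi_means[sig] = {k: float(np.nanmean(v)) if np.isfinite(v).any()
                          else np.nan
                          for k, v in ((k, np.asarray(v)) for k, v in by_roi.items())}
    return InterhemisphericResult(pair_r, roi_means)


def group_interhemispheric(results) -> pd.DataFrame:
    """Mean and standard error of ROI aggregates across subjects.

    Returns a table indexed by (signal, roi_set) with columns mean, sem, n.
    """
    rows = []
    for sig in ("HbO", "Hb"):
        for key in ("overall", "lOFC", "mOFC"):
            vals = np.asarray([res.roi_means[sig][key] for res in results])
            vals = vals[np.isfinite(vals)]
            n = len(vals)
            rows.append({"signal": sig, "roi_set": key,
                         "mean": float(np.mean(vals)) if n else np.nan,
                         "sem": float(np.std(vals, ddof=1) / np.sqrt(n))
                                if n > 1 else np.nan,
                         "n": n})
    return pd.DataFrame(rows).set_index(["signal", "roi_set"])


def subject_roi_values(results, signal: str = "HbO",
                       roi_set: str = "overall") -> np.ndarray:
    return np.asarray([res.roi_means[signal][roi_set] for res in results])


def group_mean_matrix(matrices, level: str = "group") -> ConnectivityMatrix:
    """Average subject matrices in Fisher-z space, back-transform to r.

    A channel masked for some subjects is retained at group level using the
    available subjects; a channel masked everywhere stays masked.
    """
    if not matrices:
        raise NirsconnError("no matrices to aggregate")
    labels = matrices[0].channel_labels
    zs = np.stack([m.values_z for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_z = np.nanmean(zs, axis=0)
    r = np.tanh(mean_z)
    np.fill_diagonal(r, 1.0)
    mask = np.stack([m.mask for m in matrices]).any(axis=0)
    r[~mask, :] = np.nan
    r[:, ~mask] = np.nan
    return ConnectivityMatrix(r, labels, mask=mask, level=level,
                              signal=matrices[0].signal)


def seed_rsfc_map(matrix: ConnectivityMatrix, seed) -> pd.Series:
    """The seed channel's Fisher-z row, self-entry excluded."""
    i = matrix.index_of(seed)
    if not matrix.mask[i]:
        raise NirsconnError(f"seed channel {seed} is masked")
    values = {}
    for j, label in enumerate(matrix.channel_labels):
        if j == i:
            continue
        values[label] = matrix.values_z[i, j]
    return pd.Series(values, name=f"seed_{seed}_{matrix.signal}_z")


def group_seed_map(matrices, seed) -> pd.Series:
    """Arithmetic mean of subject seed maps over subjects with a valid seed."""
    maps = []
    for m in matrices:
        i = m.index_of(seed)
        if not m.mask[i]:
            warnings.warn(f"seed {seed} masked for a subject; omitted from group map")
            continue
        maps.append(seed_rsfc_map(m, seed))
    if not maps:
        raise NirsconnError(f"seed {seed} masked for every subject")
    return pd.concat(maps, axis=1).mean(axis=1)


# ---------------------------------------------------------------------------
# Graph thresholding


@dataclass
class BrainGraph:
    """Binary adjacency at a stated sparsity or absolute cutoff."""

    adjacency: np.ndarray
    node_labels: tuple
    sparsity: float | None = None
    cutoff: float | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NirsconnError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise NirsconnError("self-loops are not allowed")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_set(self):
        a = self.adjacency
        return {(i, j) for i in range(a.shape[0])
                for j in range(i + 1, a.shape[0]) if a[i, j]}

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        for i, j in self.edge_set():
            g.add_edge(self.node_labels[i], self.node_labels[j])
        return g


def ranked_positive_pairs(matrix: ConnectivityMatrix):
    """Off-diagonal pairs with r > 0, strongest first, stable tie-break.

    The tie-break is ascending (i, j) label order at equal r, which makes
    every prefix of this list a nested family of edge sets.
    """
    entries = []
    for i, j in matrix.off_diagonal_pairs():
        r = matrix.values_r[i, j]
        if np.isfinite(r) and r > 0:
            entries.append((-r, i, j))
    entries.sort()
    return [(i, j, -negr) for negr, i, j in entries]


def _graph_from_pairs(matrix, pairs, **meta) -> BrainGraph:
    n = matrix.n
    a = np.zeros((n, n), dtype=int)
    for i, j, _ in pairs:
        a[i, j] = a[j, i] = 1
    return BrainGraph(a, matrix.channel_labels, **meta)


def threshold_absolute(matrix: ConnectivityMatrix, cutoff: float | None = None,
                       top_fraction: float | None = None) -> BrainGraph:
    """Absolute threshold: keep r > cutoff, or the top fraction of connections.

    ``top_fraction`` keeps the floor(q * N(N-1)/2) largest off-diagonal
    values (the "foremost q" rule).  Exactly one of the two modes must be
    given.
    """
    if (cutoff is None) == (top_fraction is None):
        raise ValueError("give exactly one of cutoff or top_fraction")
    ranked = ranked_positive_pairs(matrix)
    if cutoff is not None:
        kept = [(i, j, r) for i, j, r in ranked if r > cutoff]
        return _graph_from_pairs(matrix, kept, cutoff=float(cutoff))
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction {top_fraction} outside (0, 1]")
    n_possible = matrix.n * (matrix.n - 1) // 2
    k = int(np.floor(top_fraction * n_possible))
    return _graph_from_pairs(matrix, ranked[:k], sparsity=float(top_fraction))


def threshold_sparsity(matrix: ConnectivityMatrix, S: float) -> BrainGraph:
    """Relative threshold: keep the round(S * N(N-1)/2) strongest edges."""
    if not 0 <= S <= 1:
        raise ValueError(f"sparsity {S} outside [0, 1]")
    n_possible = matrix.n * (matrix.n - 1) // 2
    k = int(round(S * n_possible))
    ranked = ranked_positive_pairs(matrix)
    return _graph_from_pairs(matrix, ranked[:k], sparsity=float(S))
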