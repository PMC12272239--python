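"""Functional-network graph analysis on parcel-wise Pearson matrices.

Builds node time series and adjacency matrices, removes global nuisance
signal (4-level GSR: global mean, its temporal derivative, and both squares),
and characterizes network structure through a signed weighted modularity

    Q(gamma, {g_i}) = sum_ij [A_ij - gamma * P_ij] * delta(g_i, g_j)

optimized by an in-package Louvain algorithm and stabilized by
association-matrix consensus clustering, plus matrix reordering, density
thresholding, inter-hemispheric (homotopic) edge correlation, distance-resolved
edge weights and average strength.

Negative correlations are handled by the asymmetric signed scheme: positive
and negative subnetworks get their own configuration-model null, the positive
part is normalized by the positive total weight and the negative part
down-weighted by its share of the total, so Q stays in [-1, 1] and reduces to
the standard Newman-Girvan quality on nonnegative matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .containers import Parcellation, check_adjacency

__all__ = [
    "ModulePartition",
    "roi_timeseries",
    "bandpass",
    "connectivity",
    "gsr4",
    "modularity_Q",
    "louvain",
    "consensus_partition",
    "reorder_by_partition",
    "density_threshold",
    "interhemispheric_correlation",
    "weight_vs_distance",
    "average_strength",
    "GlobalSignalRegressor",
    "BandpassFilter",
    "LouvainCommunities",
    "ConsensusCommunities",
]


@dataclass
class ModulePartition:
    """Community assignment with the resolution and quality it was found at."""

    membership: np.ndarray   # per-node module id, contiguous from 1
    gamma: float
    q: float
    converged: bool = True

    @property
    def n_modules(self) -> int:
        return int(self.membership.max())


def roi_timeseries(data: np.ndarray, voxel_to_node: np.ndarray) -> np.ndarray:
    """Per-node mean over member voxels; errors on empty nodes."""
    data = np.asarray(data, dtype=float)
    voxel_to_node = np.asarray(voxel_to_node)
    node_ids = np.unique(voxel_to_node)
    out = np.empty((node_ids.size, data.shape[1]))
    for i, nid in enumerate(node_ids):
        members = voxel_to_node == nid
        if not members.any():  # pragma: no cover - unique() precludes it
            raise ValueError(f"node {nid} has no member voxels")
        out[i] = data[members].mean(axis=0)
    return out


def bandpass(ts: np.ndarray, low: float = 0.005, high: float = 0.12,
             tr: float = 2.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time (last) axis."""
    fs = 1.0 / tr
    nyquist = fs / 2.0
    if not 0 < low < high < nyquist:
        raise ValueError(f"band ({low}, {high}) Hz invalid for Nyquist {nyquist} Hz")
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(ts, dtype=float), axis=-1)


def connectivity(node_ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of node x time data (zero-variance -> 0)."""
    node_ts = np.asarray(node_ts, dtype=float)
    if node_ts.shape[1] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = node_ts.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance node(s): correlations set to 0")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(node_ts)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r


def gsr4(node_ts: np.ndarray) -> np.ndarray:
    """4-level global signal regression.

    Regresses out, per node, the global (node-mean) signal g, its temporal
    derivative, g squared, and the squared derivative (all demeaned, plus an
    intercept); returns the OLS residuals, orthogonal to every regressor.
    Collinear or constant regressors are dropped with a warning.
    """
    y = np.asarray(node_ts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 5:
        raise ValueError("need a node x time array with at least 5 time points")
    g = y.mean(axis=0)
    dg = np.gradient(g)
    cols = [g, dg, g**2, dg**2]
    names = ["global", "derivative", "square", "derivative_square"]
    X = [np.ones_like(g)]
    kept: list[str] = []
    for name, col in zip(names, cols):
        c = col - col.mean()
        norm = np.linalg.norm(c)
        if norm < 1e-12 * max(np.linalg.norm(g), 1.0):
            warnings.warn(f"gsr4: dropping constant regressor {name!r}")
            continue
        candidate = np.column_stack(X + [c])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            warnings.warn(f"gsr4: dropping collinear regressor {name!r}")
            continue
        X.append(c)
        kept.append(name)
    Xm = np.column_stack(X)
    beta, *_ = np.linalg.lstsq(Xm, y.T, rcond=None)
    return y - (Xm @ beta).T


# ---------------------------------------------------------------------------
# modularity and community detection
# ---------------------------------------------------------------------------

def _null_matrix(w: np.ndarray, null_model: str) -> np.ndarray:
    """Expected-weight matrix for one (nonnegative) subnetwork."""
    total = w.sum()
    if total == 0:
        return np.zeros_like(w)
    if null_model == "configuration":
        s = w.sum(axis=1)
        return np.outer(s, s) / total
    if null_model == "uniform":
        n = w.shape[0]
        return np.full_like(w, total / (n * (n - 1))) * (1 - np.eye(n))
    raise ValueError(f"unknown null model {null_model!r}")


def _modularity_matrix(a: np.ndarray, gamma: float, null_model: str) -> np.ndarray:
    """Signed modularity matrix B with Q(partition) = sum_ij B_ij delta(gi,gj).

    Self-edges are excluded (diagonal zeroed before the split into positive
    and negative parts).
    """
    a = check_adjacency(a)
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    w_pos = np.clip(a, 0, None)
    w_neg = np.clip(-a, 0, None)
    v_pos = w_pos.sum()
    v_neg = w_neg.sum()
    if v_pos == 0 and v_neg == 0:
        raise ValueError("all-zero adjacency matrix")
    b = np.zeros_like(a)
    if v_pos > 0:
        b += (w_pos - gamma * _null_matrix(w_pos, null_model)) / v_pos
    if v_neg > 0:
        b -= (w_neg - gamma * _null_matrix(w_neg, null_model)) / (v_pos + v_neg)
    return b


def _contiguous(membership: np.ndarray) -> np.ndarray:
    _, inv = np.unique(membership, return_inverse=True)
    return inv + 1


def modularity_Q(
    a: np.ndarray,
    partition: np.ndarray,
    gamma: float = 1.0,
    null_model: str = "configuration",
) -> float:
    """Signed weighted modularity of a partition.

    Evaluates ``sum_ij [A_ij - gamma P_ij] delta(g_i, g_j)`` over ordered node
    pairs (self-edges excluded), with the configuration-model null per signed
    subnetwork and the asymmetric signed normalization described in the module
    docstring.
    """
    partition = np.asarray(partition)
    if partition.shape[0] != np.asarray(a).shape[0]:
        raise ValueError("partition must cover all nodes")
    b = _modularity_matrix(a, gamma, null_model)
    same = partition[:, None] == partition[None, :]
    return float(b[same].sum())


def _louvain_membership(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain on modularity matrix ``b``; returns contiguous module ids."""
    n0 = b.shape[0]
    membership = np.arange(n0)
    level_b = b.copy()
    np.fill_diagonal(level_b, 0.0)
    while True:
        n = level_b.shape[0]
        comm = np.arange(n)
        improved = False
        moved = True
        while moved:
            moved = False
            for i in rng.permutation(n):
                row = level_b[i]
                gains = np.zeros(n + 1)  # slot n = escape to a new singleton
                np.add.at(gains, comm, 2.0 * row)
                current = comm[i]
                best = int(np.argmax(gains))
                if gains[best] > gains[current] + 1e-12 and best != current:
                    if best == n:  # empty community: pick an unused id
                        used = np.zeros(n + 1, dtype=bool)
                        used[comm] = True
                        best = int(np.nonzero(~used)[0][0])
                    comm[i] = best
                    moved = True
                    improved = True
        comm = _contiguous(comm) - 1
        k = comm.max() + 1
        if not improved or k == n:
            return _contiguous(comm[membership] if improved else membership)
        membership = comm[membership]
        onehot = np.eye(k)[comm]
        level_b = onehot.T @ level_b @ onehot
        np.fill_diagonal(level_b, 0.0)


def louvain(
    a: np.ndarray,
    gamma: float = 1.0,
    seed: int | np.random.Generator = 0,
    null_model: str = "configuration",
    restarts: int = 10,
) -> ModulePartition:
    """Louvain community detection under the signed modularity objective.

    The greedy node-moving/aggregation search is restarted ``restarts`` times
    with different random visiting orders and the best-Q partition is
    returned; the whole procedure is deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = _modularity_matrix(a, gamma, null_model)
    best_m: np.ndarray | None = None
    best_q = -np.inf
    for _ in range(max(restarts, 1)):
        membership = _louvain_membership(b, rng)
        q = float(b[membership[:, None] == membership[None, :]].sum())
        if q > best_q + 1e-15:
            best_q, best_m = q, membership
    q = modularity_Q(a, best_m, gamma, null_model)
    return ModulePartition(membership=best_m, gamma=gamma, q=q)


def consensus_partition(
    a: np.ndarray,
    gamma: float = 1.0,
    n_runs: int = 50,
    seed: int = 0,
    gamma_range: np.ndarray | None = None,
    max_iter: int = 20,
    binary_tol: float = 1e-12,
) -> tuple[ModulePartition, np.ndarray]:
    """Association-matrix consensus over stochastic Louvain runs.

    Louvain is run ``n_runs`` times (optionally sweeping ``gamma_range``), the
    node x node co-classification frequency matrix is built and re-clustered
    with the same algorithm under a permutation (uniform) null, iterating
    until the consensus matrix is block-binary.  Returns the stable partition
    (with Q evaluated on the original matrix at ``gamma``) and the final
    co-classification matrix.  Non-convergence returns the last partition
    flagged ``converged=False`` with a warning.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    gammas = np.atleast_1d(gamma_range if gamma_range is not None else gamma)
    n = np.asarray(a).shape[0]

    def run_batch(matrix: np.ndarray, null: str, batch_seed: int) -> np.ndarray:
        parts = np.empty((n_runs * gammas.size, n), dtype=int)
        k = 0
        for g in gammas:
            for r in range(n_runs):
                parts[k] = louvain(matrix, gamma=float(g), seed=batch_seed + k,
                                   null_model=null).membership
                k += 1
        return parts

    parts = run_batch(a, "configuration", seed)
    coclass = np.mean(parts[:, :, None] == parts[:, None, :], axis=0).astype(float)
    converged = False
    membership = parts[0]
    for it in range(max_iter):
        binary = np.all((coclass < binary_tol) | (coclass > 1 - binary_tol))
        if binary:
            membership = _components_of(coclass > 0.5)
            converged = True
            break
        parts = run_batch(coclass, "uniform", seed + 7919 * (it + 1))
        membership = parts[0]
        coclass = np.mean(parts[:, :, None] == parts[:, None, :], axis=0).astype(float)
    if not converged:
        warnings.warn("consensus did not reach a block-binary matrix; "
                      "returning last partition")
        membership = _contiguous(membership)
    q = modularity_Q(a, membership, gamma)
    return ModulePartition(membership=membership, gamma=gamma, q=q,
                           converged=converged), coclass


def _components_of(adj_bool: np.ndarray) -> np.ndarray:
    """Connected components of a boolean adjacency; contiguous ids from 1."""
    n = adj_bool.shape[0]
    labels = np.zeros(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj_bool[u])[0]:
                if not labels[v]:
                    labels[v] = current
                    stack.append(v)
    return labels


def reorder_by_partition(a: np.ndarray, partition: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permute rows/columns so modules are contiguous (module id, then node id).

    Returns the reordered matrix and the permutation applied.
    """
    a = check_adjacency(a)
    partition = np.asarray(partition)
    if partition.shape[0] != a.shape[0]:
        raise ValueError("partition does not match the matrix nodes")
    order = np.lexsort((np.arange(a.shape[0]), partition))
    return a[np.ix_(order, order)], order


def density_threshold(a: np.ndarray, p: float = 0.2) -> np.ndarray:
    """Keep the ceil(p * E) strongest off-diagonal edges, zero the rest.

    E = n(n-1)/2 unique pairs; retained weights are unchanged and ties at the
    cutoff are broken deterministically by (i, j) lexicographic order.
    """
    if not 0 < p <= 1:
        raise ValueError("density p must lie in (0, 1]")
    a = check_adjacency(a)
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k = int(np.ceil(p * iu.size))
    order = np.lexsort((ju, iu, -a[iu, ju]))  # weight desc, then (i, j)
    keep = order[:k]
    out = np.zeros_like(a)
    out[iu[keep], ju[keep]] = a[iu[keep], ju[keep]]
    out = out + out.T
    np.fill_diagonal(out, np.diag(a))
    return out


def interhemispheric_correlation(a: np.ndarray, parcellation: Parcellation) -> dict:
    """Homotopic-edge correspondence between hemispheres.

    Every unique within-left edge (i, j) is paired with the homologous
    within-right edge (partner(i), partner(j)); returns Spearman rho, its
    p-value and the least-squares line over all pairs, plus the paired edge
    weights.
    """
    a = check_adjacency(a)
    if a.shape[0] != parcellation.n_nodes:
        raise ValueError("matrix size does not match the parcellation")
    left = np.nonzero(parcellation.hemisphere_mask("L"))[0]
    partner = parcellation.partner_positions()
    lw, rw = [], []
    for ii in range(left.size):
        for jj in range(ii + 1, left.size):
            i, j = left[ii], left[jj]
            lw.append(a[i, j])
            rw.append(a[partner[i], partner[j]])
    lw = np.asarray(lw)
    rw = np.asarray(rw)
    rho, pval = stats.spearmanr(lw, rw)
    fit = stats.linregress(lw, rw)
    return {
        "rho": float(rho),
        "p_value": float(pval),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "left_weights": lw,
        "right_weights": rw,
    }


def weight_vs_distance(a: np.ndarray, parcellation: Parcellation,
                       n_bins: int = 10) -> tuple[pd.DataFrame, dict]:
    """Edge weight as a function of inter-node Euclidean distance.

    Returns a per-edge table (distance mm, weight, intra-hemispheric flag)
    and a summary with mean weight per distance decile and the Spearman
    rho(weight, distance).
    """
    a = check_adjacency(a)
    cent = parcellation.centroids()
    hemi = parcellation.table["hemisphere"].to_numpy()
    iu, ju = np.triu_indices(a.shape[0], k=1)
    dist = np.linalg.norm(cent[iu] - cent[ju], axis=1)
    table = pd.DataFrame(
        {
            "distance_mm": dist,
            "weight": a[iu, ju],
            "intra_hemispheric": hemi[iu] == hemi[ju],
        }
    )
    if np.ptp(dist) > 0:
        bins = pd.qcut(table["distance_mm"], q=n_bins, duplicates="drop")
        binned = table.groupby(bins, observed=True)["weight"].mean()
        rho = float(stats.spearmanr(table["weight"], table["distance_mm"]).statistic)
    else:  # degenerate geometry: all centroids coincide
        binned = pd.Series({pd.Interval(0.0, 0.0, closed="both"): table["weight"].mean()})
        rho = float("nan")
    intra = table[table["intra_hemispheric"]]
    rho_intra = (
        float(stats.spearmanr(intra["weight"], intra["distance_mm"]).statistic)
        if len(intra) > 2 and np.ptp(intra["distance_mm"]) > 0 else float("nan")
    )
    summary = {"bin_mean_weight": binned, "spearman_rho": rho,
               "spearman_rho_intra": rho_intra}
    return table, summary


def average_strength(a: np.ndarray) -> float:
    """Mean off-diagonal edge weight."""
    a = check_adjacency(a)
    n = a.shape[0]
    return float((a.sum() - np.trace(a)) / (n * (n - 1)))


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class GlobalSignalRegressor(TransformerMixin, BaseEstimator):
    """Transformer applying 4-level GSR to node x time data."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return gsr4(np.asarray(X, dtype=float))


class BandpassFilter(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth band-pass over the time axis of node x time data."""

    def __init__(self, low: float = 0.005, high: float = 0.12,
                 tr: float = 2.0, order: int = 4):
        self.low = low
        self.high = high
        self.tr = tr
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return bandpass(X, self.low, self.high, self.tr, self.order)


class LouvainCommunities(ClusterMixin, BaseEstimator):
    """Louvain community detection over a signed adjacency matrix.

    ``fit(A)`` sets ``labels_`` (module ids from 1), ``q_`` and ``n_modules_``.
    """

    def __init__(self, gamma: float = 1.0, seed: int = 0,
                 null_model: str = "configuration"):
        self.gamma = gamma
        self.seed = seed
        self.null_model = null_model

    def fit(self, X, y=None):
        part = louvain(X, gamma=self.gamma, seed=self.seed, null_model=self.null_model)
        self.labels_ = part.membership
        self.q_ = part.q
        self.n_modules_ = part.n_modules
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class ConsensusCommunities(ClusterMixin, BaseEstimator):
    """Consensus (association-matrix) community detection.

    ``fit(A)`` sets ``labels_``, ``q_``, ``n_modules_``, ``converged_`` and
    the final co-classification matrix ``coclassification_``.
    """

    def __init__(self, gamma: float = 1.0, n_runs: int = 50, seed: int = 0,
                 gamma_range=None, max_iter: int = 20):
        self.gamma = gamma
        self.n_runs = n_runs
        self.seed = seed
        self.gamma_range = gamma_range
        self.max_iter = max_iter

    def fit(self, X, y=None):
        part, coclass = consensus_partition(
            X, gamma=self.gamma, n_runs=self.n_runs, seed=self.seed,
            gamma_range=self.gamma_range, max_iter=self.max_iter,
        )
        self.labels_ = part.membership
        self.q_ = part.q
        self.n_modules_ = part.n_modules
        self.converged_ = part.converged
        self.coclassification_ = coclass
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
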