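"""Ensemble detection: functional-connectivity graph + modularity clustering.

Neurons whose activity vectors are correlated are functionally connected.
The pipeline builds a weighted graph over neurons in three steps:

1. pairwise correlation distance ``d_ij = 1 - r_ij`` between binary
   activity vectors (``r`` is the Pearson correlation, which on 0/1 rows
   equals the phi coefficient);
2. a local fuzzy k-nearest-neighbor graph: each neuron's distances to its
   ``k`` nearest neighbors are turned into membership weights
   ``w_ij = exp(-max(0, d_ij - rho_i) / sigma_i)`` with ``rho_i`` the
   distance to the nearest neighbor and ``sigma_i`` calibrated so the
   local weights sum to ``log2(k)``;
3. symmetrization by probabilistic union ``w_ij + w_ji - w_ij * w_ji``,
   giving a symmetric matrix of connection probabilities in [0, 1].

Ensembles are then the communities of that graph under Newman's
leading-eigenvector modularity method: recursive spectral bisection of the
(generalized) modularity matrix, with Kernighan-Lin style single-vertex
refinement of each split, stopping when no division contributes positive
modularity. A consensus wrapper stabilizes the partition across seeded
weight-jittered re-runs via the co-assignment matrix.

:class:`EnsembleDetector` packages the whole chain as a scikit-learn
clusterer (``fit`` / ``fit_predict`` / ``labels_``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse.linalg
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .raster import Raster

__all__ = [
    "EmbeddingParams",
    "AdjacencyGraph",
    "ModularityMatrix",
    "EnsembleAssignment",
    "EnsembleDetector",
    "correlation_distance",
    "zero_variance_neurons",
    "fuzzy_knn_graph",
    "modularity_matrix",
    "detect_communities",
    "partition_modularity",
    "sort_raster",
    "embed",
]

#: numerical tolerance for eigenvalue positivity / modularity improvements
_EIG_TOL = 1e-9


@dataclass(frozen=True)
class EmbeddingParams:
    """Parameters of the neighbor graph and the low-dimensional projection.

    ``n_neighbors`` and ``metric`` shape the high-dimensional graph (small
    neighbor counts preserve fine local structure, which is what resolves
    individual ensembles); ``min_dist`` and ``n_components`` only matter
    for the visualization embedding.
    """

    n_neighbors: int = 10
    metric: str = "correlation"
    min_dist: float = 0.1
    n_components: int = 2

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if self.metric != "correlation":
            raise ValueError("only the correlation metric is supported")


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric weighted functional-connectivity graph.

    ``weights[i, j]`` is the probability that nodes i and j are
    functionally connected; zero diagonal, entries in [0, 1].
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if (w < -1e-12).any() or (w > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")
        w = np.clip(w, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return int(self.weights.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m: total edge weight (each undirected edge counted once)."""
        return float(self.weights.sum() / 2.0)


@dataclass(frozen=True)
class ModularityMatrix:
    """Modularity matrix ``B`` (full) or ``B^(g)`` (group-restricted).

    Full form: ``B_ij = A_ij - k_i k_j / (2m)``; every row sums to zero.
    Restricted to a node subset ``g``:
    ``B^(g)_ij = B_ij - delta_ij * sum_{k in g} B_ik``, the form whose
    leading eigenvector drives further bisection of a subgraph.
    """

    entries: np.ndarray
    degrees: np.ndarray
    total_weight: float
    group: Optional[Tuple[int, ...]] = None


def zero_variance_neurons(matrix: np.ndarray) -> np.ndarray:
    """Indices of rows that are constant (all-zero / all-one activity).

    Pearson correlation is undefined for such neurons, so they cannot be
    placed in the connectivity graph.
    """
    matrix = np.asarray(matrix)
    sums = matrix.sum(axis=1)
    return np.flatnonzero((sums == 0) | (sums == matrix.shape[1]))


def correlation_distance(raster) -> np.ndarray:
    """Pairwise correlation distance ``d_ij = 1 - r_ij`` between neurons.

    Returns an ``(N, N)`` symmetric matrix with ``d in [0, 2]`` and a zero
    diagonal. Rows/columns of zero-variance neurons are NaN and a warning
    names them; downstream graph construction must exclude them.
    """
    matrix = raster.matrix if isinstance(raster, Raster) else np.asarray(raster)
    if matrix.shape[0] < 2:
        raise ValueError("need at least two neurons for pairwise distances")
    bad = zero_variance_neurons(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(matrix.astype(float))
    d = 1.0 - r
    if bad.size:
        warnings.warn(
            f"{bad.size} zero-variance neuron(s) excluded from graph "
            f"construction: {bad.tolist()}",
            stacklevel=2,
        )
        d[bad, :] = np.nan
        d[:, bad] = np.nan
    valid = np.setdiff1d(np.arange(matrix.shape[0]), bad)
    d[np.ix_(valid, valid)] = np.clip(d[np.ix_(valid, valid)], 0.0, 2.0)
    d[valid, valid] = 0.0
    return d


def _smooth_knn_sigma(dists: np.ndarray, target: float, tol: float = 1e-5,
                      max_iter: int = 64) -> float:
    """Solve ``sum_j exp(-dists_j / sigma) = target`` for sigma by bisection.

    ``dists`` are the non-negative rho-shifted neighbor distances. Terms
    with ``dists_j == 0`` contribute 1 regardless of sigma; when even
    ``sigma -> 0`` cannot reach down to the target the smallest sigma is
    returned (all-equidistant degenerate neighborhoods).
    """
    lo, hi = 1e-12, 1.0
    def total(sigma: float) -> float:
        return float(np.exp(-dists / sigma).sum())
    # total() is increasing in sigma; expand hi until it brackets.
    for _ in range(64):
        if total(hi) >= target:
            break
        hi *= 2.0
    if total(lo) >= target:
        return lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if abs(total(mid) - target) < tol:
            return mid
        if total(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fuzzy_knn_graph(distances: np.ndarray, params: Optional[EmbeddingParams] = None,
                    n_neighbors: Optional[int] = None) -> AdjacencyGraph:
    """Fuzzy k-nearest-neighbor graph from a pairwise distance matrix.

    For each node the ``k`` nearest neighbors (ties broken by lower index)
    get directed weights ``exp(-max(0, d - rho_i) / sigma_i)`` where
    ``rho_i`` is the nearest-neighbor distance and ``sigma_i`` normalizes
    the local weight sum to ``log2(k)``; directed weights are merged by
    probabilistic union into a symmetric graph.
    """
    if params is None:
        params = EmbeddingParams(n_neighbors=n_neighbors or 10)
    elif n_neighbors is not None:
        raise ValueError("pass n_neighbors via params or standalone, not both")
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if np.isnan(d).any():
        raise ValueError(
            "distance matrix contains NaN (zero-variance neurons?); "
            "exclude them before building the graph"
        )
    n = d.shape[0]
    k = params.n_neighbors
    if k >= n:
        raise ValueError(f"n_neighbors={k} must be < number of nodes ({n})")
    target = float(np.log2(k))
    directed = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        # stable sort on distance => ties broken by lower neuron index
        order = others[np.argsort(d[i, others], kind="stable")][:k]
        nd = d[i, order]
        rho = nd[0]
        shifted = np.maximum(0.0, nd - rho)
        sigma = _smooth_knn_sigma(shifted, target)
        directed[i, order] = np.exp(-shifted / sigma)
    w = directed + directed.T - directed * directed.T
    return AdjacencyGraph(w)


def modularity_matrix(graph: AdjacencyGraph,
                      group: Optional[Sequence[int]] = None) -> ModularityMatrix:
    """Modularity matrix of ``graph``, optionally restricted to ``group``."""
    m = graph.total_weight
    if m <= 0:
        raise ValueError("graph has no edges")
    k = graph.degrees
    b_full = graph.weights - np.outer(k, k) / (2.0 * m)
    if group is None:
        return ModularityMatrix(b_full, k, m, None)
    idx = np.asarray(list(group), dtype=int)
    sub = b_full[np.ix_(idx, idx)]
    bg = sub - np.diag(sub.sum(axis=1))
    return ModularityMatrix(bg, k[idx], m, tuple(int(i) for i in idx))


def _leading_eigenpair(b: np.ndarray) -> Tuple[float, np.ndarray]:
    """Largest-eigenvalue pair of a symmetric matrix, with dense fallback."""
    n = b.shape[0]
    if n > 256:
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(b, k=1, which="LA")
            return float(vals[0]), vecs[:, 0]
        except (scipy.sparse.linalg.ArpackNoConvergence, ValueError):
            pass
    vals, vecs = scipy.linalg.eigh(b)
    return float(vals[-1]), vecs[:, -1]


def _refine_split(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style single-vertex refinement of a sign vector.

    Repeated sweeps: every vertex is moved once per sweep (largest gain
    first, gains may be negative), and the best intermediate state of the
    sweep is kept if it improves ``s^T B^(g) s``.
    """
    n = bg.shape[0]
    s = s.astype(float).copy()
    best_val = float(s @ bg @ s)
    for _ in range(n):  # at most n sweeps; usually converges in 1-2
        trial = s.copy()
        val = best_val
        states = []
        moved = np.zeros(n, dtype=bool)
        for _step in range(n):
            # gain of flipping vertex i: -4 s_i (B s)_i + 4 B_ii
            bs = bg @ trial
            gains = -4.0 * trial * bs + 4.0 * np.diag(bg)
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            trial[i] = -trial[i]
            moved[i] = True
            val += gains[i]
            states.append((val, trial.copy()))
        sweep_best_val, sweep_best = max(states, key=lambda t: t[0])
        if sweep_best_val > best_val + _EIG_TOL:
            best_val, s = sweep_best_val, sweep_best
        else:
            break
    return s


def _bisect_recursive(b_full: np.ndarray, m: float, idx: np.ndarray,
                      communities: list) -> None:
    """Recursive leading-eigenvector bisection over node subset ``idx``."""
    if idx.size < 2:
        communities.append(idx)
        return
    sub = b_full[np.ix_(idx, idx)]
    bg = sub - np.diag(sub.sum(axis=1))
    lam, vec = _leading_eigenpair(bg)
    if lam <= _EIG_TOL:
        communities.append(idx)
        return
    s = np.where(vec >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        communities.append(idx)
        return
    s = _refine_split(bg, s)
    if np.all(s == s[0]):
        communities.append(idx)
        return
    delta_q = float(s @ bg @ s) / (4.0 * m)
    if delta_q <= _EIG_TOL:
        communities.append(idx)
        return
    _bisect_recursive(b_full, m, idx[s > 0], communities)
    _bisect_recursive(b_full, m, idx[s < 0], communities)


def partition_modularity(graph: AdjacencyGraph, labels: np.ndarray) -> float:
    """Standard modularity Q of a labeling: ``(1/2m) sum_ij B_ij delta``."""
    m = graph.total_weight
    if m <= 0:
        raise ValueError("graph has no edges")
    b = modularity_matrix(graph).entries
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum() / (2.0 * m))


@dataclass(frozen=True)
class EnsembleAssignment:
    """Neuron -> community labels with the partition's modularity.

    ``labels[i]`` is the ensemble id of neuron ``i`` (contiguous from 0);
    ``-1`` marks neurons excluded from graph construction (zero-variance
    rows). ``order`` holds community ids sorted by first appearance and is
    filled by :func:`sort_raster` / peak detection.
    """

    labels: np.ndarray
    modularity_q: float
    order: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        present = np.unique(labels[labels >= 0])
        if present.size and not np.array_equal(present, np.arange(present.size)):
            raise ValueError("community ids must be contiguous from 0")
        if not np.isfinite(self.modularity_q):
            raise ValueError("modularity_q must be finite")
        object.__setattr__(self, "labels", labels)

    @property
    def n_ensembles(self) -> int:
        labels = self.labels[self.labels >= 0]
        return int(labels.max() + 1) if labels.size else 0

    def members(self, ensemble: int) -> np.ndarray:
        return np.flatnonzero(self.labels == ensemble)


def _single_detection(weights: np.ndarray) -> np.ndarray:
    """One pass of recursive leading-eigenvector bisection -> labels."""
    graph = AdjacencyGraph(weights)
    m = graph.total_weight
    if m <= 0:
        return np.arange(weights.shape[0])  # singletons
    b_full = modularity_matrix(graph).entries
    communities: list = []
    _bisect_recursive(b_full, m, np.arange(weights.shape[0]), communities)
    labels = np.empty(weights.shape[0], dtype=int)
    for cid, members in enumerate(communities):
        labels[members] = cid
    return labels


def detect_communities(graph: AdjacencyGraph, consensus_runs: int = 10,
                       seed: int = 0, jitter: float = 0.01,
                       coassignment_threshold: float = 0.5,
                       max_cycles: int = 20) -> EnsembleAssignment:
    """Consensus leading-eigenvector community detection.

    The base algorithm is re-run ``consensus_runs`` times (the first run on
    the unperturbed graph, later runs with each edge weight multiplied by
    ``1 + u``, ``u ~ U[-jitter, jitter]``, seeded). The co-assignment
    matrix (fraction of runs placing i and j together) is thresholded and
    re-clustered until it is binary-stable; final labels come from its
    connected components and Q is evaluated on the original graph.
    """
    if consensus_runs < 1:
        raise ValueError("consensus_runs must be >= 1")
    if graph.total_weight <= 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    weights = graph.weights
    for _cycle in range(max_cycles):
        runs = []
        for r in range(consensus_runs):
            if r == 0:
                w = weights
            else:
                u = rng.uniform(-jitter, jitter, size=(n, n))
                u = np.triu(u, 1)
                u = u + u.T
                w = np.clip(weights * (1.0 + u), 0.0, None)
                w = np.clip(w, 0.0, 1.0)
            runs.append(_single_detection(w))
        coassign = np.zeros((n, n))
        for labels in runs:
            coassign += labels[:, None] == labels[None, :]
        coassign /= len(runs)
        binary = (coassign <= 1e-12) | (coassign >= 1 - 1e-12)
        if binary.all():
            break
        weights = np.where(coassign > coassignment_threshold, coassign, 0.0)
        np.fill_diagonal(weights, 0.0)
        if weights.sum() <= 0:
            # no stable pairs at all: every node its own community
            labels = np.arange(n)
            return EnsembleAssignment(labels, partition_modularity(graph, labels))
    # connected components of the final co-assignment agreement
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    agree = coassign > coassignment_threshold
    np.fill_diagonal(agree, True)
    _, labels = connected_components(sp.csr_matrix(agree), directed=False)
    # relabel by first occurrence for determinism
    _, labels = np.unique(labels, return_inverse=True)
    return EnsembleAssignment(labels, partition_modularity(graph, labels))


class EnsembleDetector(BaseEstimator, ClusterMixin):
    """Detect neuronal ensembles in a binary raster (scikit-learn API).

    Chains correlation distances, the fuzzy k-nearest-neighbor
    connectivity graph, and consensus leading-eigenvector modularity
    clustering. Samples are neurons (rows of the raster).

    Parameters
    ----------
    n_neighbors : int, default 10
        Neighborhood size of the fuzzy kNN graph. Small values preserve
        the fine local structure that separates individual ensembles.
    consensus_runs : int, default 10
        Number of jittered detection runs entering the consensus.
    jitter : float, default 0.01
        Half-width of the multiplicative edge-weight jitter.
    random_state : int, default 0
        Seed for the consensus jitter.

    Attributes
    ----------
    labels_ : ndarray of shape (n_neurons,)
        Ensemble id per neuron; ``-1`` for zero-variance neurons that were
        excluded from graph construction.
    n_ensembles_ : int
    modularity_q_ : float
        Modularity of the final partition on the connectivity graph.
    graph_ : AdjacencyGraph
        Connectivity graph over the included neurons.
    excluded_ : ndarray
        Indices of excluded zero-variance neurons.
    """

    def __init__(self, n_neighbors: int = 10, consensus_runs: int = 10,
                 jitter: float = 0.01, random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.consensus_runs = consensus_runs
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, X, y=None) -> "EnsembleDetector":
        matrix = X.matrix if isinstance(X, Raster) else np.asarray(X)
        if matrix.ndim != 2:
            raise ValueError("X must be a Raster or a 2-D binary matrix")
        n = matrix.shape[0]
        excluded = zero_variance_neurons(matrix)
        included = np.setdiff1d(np.arange(n), excluded)
        if included.size <= self.n_neighbors:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} requires more than "
                f"{self.n_neighbors} non-constant neurons (have {included.size})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = correlation_distance(matrix)
        d_valid = d[np.ix_(included, included)]
        self.graph_ = fuzzy_knn_graph(
            d_valid, EmbeddingParams(n_neighbors=self.n_neighbors)
        )
        assignment = detect_communities(
            self.graph_,
            consensus_runs=self.consensus_runs,
            seed=self.random_state,
            jitter=self.jitter,
        )
        labels = np.full(n, -1, dtype=int)
        labels[included] = assignment.labels
        self.labels_ = labels
        self.excluded_ = excluded
        self.modularity_q_ = assignment.modularity_q
        self.n_ensembles_ = assignment.n_ensembles
        self.assignment_ = EnsembleAssignment(labels, assignment.modularity_q)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def sort_raster(raster: Raster, assignment: EnsembleAssignment) -> Tuple[Raster, np.ndarray]:
    """Reorder neurons by community, communities by first activation.

    Communities are placed in order of the first frame at which any member
    is active; excluded (label ``-1``) neurons are appended last. Returns
    the sorted raster and the permutation ``perm`` such that
    ``sorted.matrix[r] == raster.matrix[perm[r]]``.
    """
    labels = assignment.labels
    if labels.shape[0] != raster.n_neurons:
        raise ValueError(
            f"assignment covers {labels.shape[0]} neurons, raster has "
            f"{raster.n_neurons}"
        )
    first_active = np.full(raster.n_neurons, raster.n_frames)
    for i in range(raster.n_neurons):
        active = np.flatnonzero(raster.matrix[i])
        if active.size:
            first_active[i] = active[0]
    order = []
    community_order = []
    for cid in sorted(
        range(assignment.n_ensembles),
        key=lambda c: (int(first_active[labels == c].min()), c),
    ):
        members = np.flatnonzero(labels == cid)
        order.extend(members.tolist())
        community_order.append(cid)
    order.extend(np.flatnonzero(labels == -1).tolist())
    perm = np.asarray(order, dtype=int)
    sorted_raster = Raster(
        raster.matrix[perm],
        fps=raster.fps,
        neuron_ids=tuple(raster.neuron_ids[i] for i in perm),
    )
    return sorted_raster, perm


def embed(vectors: np.ndarray, params: Optional[EmbeddingParams] = None,
          seed: int = 0) -> np.ndarray:
    """Project activity/population vectors to 2-3 dimensions for plotting.

    Delegates to the UMAP reference implementation; coordinates are for
    visualization only and feed no downstream stage. Deterministic for a
    fixed ``seed``.
    """
    if params is None:
        params = EmbeddingParams()
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} vectors, "
            f"got {vectors.shape[0]}"
        )
    import umap  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=params.n_neighbors,
            metric=params.metric,
            min_dist=params.min_dist,
            n_components=params.n_components,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(vectors))
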