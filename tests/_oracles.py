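"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately naive: exhaustive enumeration and explicit nested
loops, sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def exhaustive_modularity_partition(weights: np.ndarray, tol: float = 1e-9):
    """Best recursive-bisection partition by exhaustive search.

    At every stage, all 2^(n-1)-1 nontrivial sign vectors of the current
    subgraph are scored on the generalized modularity matrix; the best is
    applied if its modularity contribution is positive, then both halves
    are recursed. Returns (labels, Q) with Q the standard modularity.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    m = w.sum() / 2.0
    k = w.sum(axis=1)
    b = w - np.outer(k, k) / (2.0 * m)

    communities = []

    def best_bipartition(idx):
        sub = b[np.ix_(idx, idx)]
        bg = sub - np.diag(sub.sum(axis=1))
        nn = len(idx)
        best_val, best_s = -np.inf, None
        for mask in range(1, 2 ** (nn - 1)):
            s = np.array(
                [1.0] + [1.0 if (mask >> i) & 1 else -1.0 for i in range(nn - 1)]
            )
            val = float(s @ bg @ s)
            if val > best_val:
                best_val, best_s = val, s
        return best_val / (4.0 * m), best_s

    def recurse(idx):
        if len(idx) < 2:
            communities.append(idx)
            return
        dq, s = best_bipartition(idx)
        if dq <= tol:
            communities.append(idx)
            return
        recurse(idx[s > 0])
        recurse(idx[s < 0])

    recurse(np.arange(n))
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(communities):
        labels[members] = cid
    same = labels[:, None] == labels[None, :]
    q = float(b[same].sum() / (2.0 * m))
    return labels, q


def rqa_oracle(P: np.ndarray, min_line: int = 2, include_loi: bool = True):
    """RR/DET/DIV/LAM/W by explicit scanning of every diagonal and column.

    Returns a dict of the five measures. Pure-python run counting.
    """
    P = np.asarray(P).astype(int)
    n = P.shape[0]
    Pc = P.copy()
    if not include_loi:
        for i in range(n):
            Pc[i, i] = 0
    n_points = int(Pc.sum())
    rr = n_points / (n * n)

    def runs_of_ones(values):
        lengths = []
        current = 0
        for v in values:
            if v:
                current += 1
            else:
                if current:
                    lengths.append(current)
                current = 0
        if current:
            lengths.append(current)
        return lengths

    diag_lengths = []
    for offset in range(-(n - 1), n):
        diag = [Pc[i, i + offset] for i in range(max(0, -offset), min(n, n - offset))]
        diag_lengths.extend(runs_of_ones(diag))
    vert_lengths = []
    white_lengths = []
    for j in range(n):
        vert_lengths.extend(runs_of_ones(Pc[:, j]))
        white_lengths.extend(runs_of_ones(1 - P[:, j]))

    det = (
        sum(l for l in diag_lengths if l >= min_line) / n_points
        if n_points else 0.0
    )
    lam = (
        sum(l for l in vert_lengths if l >= min_line) / n_points
        if n_points else 0.0
    )
    longest = max(diag_lengths) if diag_lengths else 0
    div = 1.0 / longest if longest else float("nan")
    w = sum(white_lengths) / len(white_lengths) if white_lengths else 0.0
    return {"RR": rr, "DET": det, "DIV": div, "LAM": lam, "W_mean": w}


def small_graph_suite(seed: int = 0):
    """Named weighted graphs of <= 10 nodes for oracle comparisons."""
    rng = np.random.default_rng(seed)
    graphs = {}

    def disconnected_cliques(sizes):
        n = sum(sizes)
        w = np.zeros((n, n))
        start = 0
        for size in sizes:
            w[start : start + size, start : start + size] = 1.0
            start += size
        np.fill_diagonal(w, 0.0)
        return w

    graphs["two_triangles"] = disconnected_cliques([3, 3])
    graphs["two_4cliques"] = disconnected_cliques([4, 4])
    graphs["cliques_5_3"] = disconnected_cliques([5, 3])
    for n in (5, 6, 8):
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        graphs[f"ring_{n}"] = w
    for n in (6, 8):
        w = np.ones((n, n))
        np.fill_diagonal(w, 0.0)
        graphs[f"complete_{n}"] = w
    for trial in range(3):
        n = 8
        labels = np.array([0] * 4 + [1] * 4)
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p_in = 0.9 if labels[i] == labels[j] else 0.15
                if rng.random() < p_in:
                    w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
        if w.sum() == 0:
            continue
        graphs[f"planted_{trial}"] = w
    for trial in range(3):
        n = int(rng.integers(4, 10))
        w = np.triu(rng.uniform(0.0, 1.0, (n, n)) * (rng.random((n, n)) < 0.5), 1)
        w = w + w.T
        if w.sum() == 0:
            w[0, 1] = w[1, 0] = 1.0
        graphs[f"random_{trial}"] = w
    return graphs
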