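"""Independent brute-force oracles for weighted graph metrics.

Shortest paths are found by exhaustive enumeration of all simple paths
(every permutation of intermediate nodes); clustering by direct triple
loops.  No code is shared with the implementation under test.
"""

from functools import lru_cache
from itertools import permutations

import numpy as np


@lru_cache(maxsize=None)
def _perm_arrays(n: int, r: int) -> np.ndarray:
    """All r-permutations of range(n) as an array (cached)."""
    if r == 0:
        return np.empty((1, 0), dtype=int)
    return np.array(list(permutations(range(n), r)), dtype=int)


def brute_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths (length = 1/weight) by enumerating
    every simple path between each node pair."""
    W = np.asarray(W, float)
    K = W.shape[0]
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    D = np.full((K, K), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            inner = np.array([n for n in range(K) if n not in (i, j)],
                             dtype=int)
            best = L[i, j]
            for r in range(1, len(inner) + 1):
                mids = inner[_perm_arrays(len(inner), r)]
                paths = np.hstack([
                    np.full((len(mids), 1), i), mids,
                    np.full((len(mids), 1), j)])
                tot = L[paths[:, :-1], paths[:, 1:]].sum(axis=1)
                m = tot.min()
                if m < best:
                    best = m
            D[i, j] = best
    return D


def brute_metrics(W: np.ndarray) -> dict[str, float]:
    """The five weighted topology measures, computed the slow exact way."""
    W = np.asarray(W, float)
    K = W.shape[0]
    D = brute_shortest_paths(W)
    off = ~np.eye(K, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    L_net = d[finite].mean() if finite.any() else np.inf
    E_global = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0).mean()
    S = W.sum() / K
    C = np.zeros(K)
    E_loc = np.zeros(K)
    for i in range(K):
        nbrs = [j for j in range(K) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0.0
        for j in nbrs:
            for l in nbrs:
                if l != j:
                    tri += (W[i, j] * W[i, l] * W[j, l]) ** (1 / 3)
        C[i] = tri / (k * (k - 1))
        sub = W[np.ix_(nbrs, nbrs)]
        Dsub = brute_shortest_paths(sub)
        offs = ~np.eye(k, dtype=bool)
        ds = Dsub[offs]
        fin = np.isfinite(ds)
        E_loc[i] = np.where(fin, 1.0 / np.where(fin, ds, 1.0), 0.0).mean()
    return dict(L_net=float(L_net), S=float(S), E_global=float(E_global),
                E_local=float(E_loc.mean()), C_net=float(C.mean()))


def random_graph(K: int, rng: np.random.Generator,
                 density: float = 0.7) -> np.ndarray:
    """Symmetric nonnegative weight matrix with U(0.05, 1] weights."""
    W = np.zeros((K, K))
    iu = np.triu_indices(K, 1)
    w = rng.uniform(0.05, 1.0, size=len(iu[0]))
    w[rng.uniform(size=len(w)) > density] = 0.0
    W[iu] = w
    return W + W.T
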