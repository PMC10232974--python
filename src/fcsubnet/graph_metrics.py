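"""Weighted graph-topology metrics for whole-brain and subnetwork graphs.

Five measures on an undirected, weighted graph with weights
``w_ij = |Pearson r|`` in [0, 1] and no self-loops:

* characteristic path length ``L_net``: mean shortest-path length over node
  pairs, with edge lengths ``1/w`` (strong correlations are short) —
  disconnected pairs are excluded from the mean and flagged;
* network strength ``S``: mean nodal strength, i.e. ``(1/N) sum_{i != j} w_ij``
  (each edge counted from both endpoints);
* global efficiency ``E_global``: mean of ``1/L_ij`` over pairs, zero for
  disconnected pairs;
* local efficiency ``E_local``: node mean of the efficiency of each node's
  neighbor subgraph with the node itself removed;
* clustering coefficient ``C_net``: node mean of the Onnela weighted
  clustering ``C_i = 2/(k_i(k_i-1)) * sum_{j<k} (w_ij w_ik w_jk)^{1/3}``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .fc_io import ConnectivityMatrix, CohortStack, EdgeIndexMap
from .group_stats import ttest_and_effect
from .pruning import Subnetwork

METRIC_NAMES = ("L_net", "S", "E_global", "E_local", "C_net")


@dataclasses.dataclass
class GraphMetricSet:
    L_net: float
    S: float
    E_global: float
    E_local: float
    C_net: float
    has_disconnected_pairs: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _weight_matrix(values: np.ndarray) -> np.ndarray:
    W = np.abs(np.asarray(values, dtype=float))
    np.fill_diagonal(W, 0.0)
    return W


def whole_brain_graph(matrix: ConnectivityMatrix) -> np.ndarray:
    """Absolute FC weights, zero diagonal; no thresholding or binarization."""
    return _weight_matrix(matrix.values)


def subnetwork_graph(matrix: ConnectivityMatrix,
                     subnetwork: Subnetwork) -> np.ndarray:
    """Original |FC| at the retained edge positions, zero elsewhere."""
    K = matrix.K
    emap = EdgeIndexMap(K)
    if subnetwork.edge_mask.size != emap.E:
        raise ValueError("subnetwork and matrix disagree on K")
    W = np.zeros((K, K))
    vals = np.abs(emap.vectorize(matrix.values))
    keep = subnetwork.edge_mask
    W[emap.rows[keep], emap.cols[keep]] = vals[keep]
    W[emap.cols[keep], emap.rows[keep]] = vals[keep]
    return W


def _pairwise_lengths(W: np.ndarray, weight_to_length: str) -> np.ndarray:
    if weight_to_length == "reciprocal":
        with np.errstate(divide="ignore"):
            lengths = np.where(W > 0, 1.0 / W, 0.0)
    elif weight_to_length == "identity":
        lengths = W.copy()
    else:
        raise ValueError(f"unknown weight_to_length {weight_to_length!r}")
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def path_metrics(W: np.ndarray,
                 weight_to_length: str = "reciprocal") -> tuple[float, float, bool]:
    """(L_net, E_global, any_disconnected) over all ordered node pairs."""
    W = _weight_matrix(W)
    K = W.shape[0]
    if K < 2:
        raise ValueError("path metrics need at least 2 nodes")
    D = _pairwise_lengths(W, weight_to_length)
    off = ~np.eye(K, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    disconnected = bool(~finite.all())
    L_net = float(d[finite].mean()) if finite.any() else float("inf")
    inv = np.zeros_like(d)
    pos = finite & (d > 0)
    inv[pos] = 1.0 / d[pos]
    E_global = float(inv.mean())
    return L_net, E_global, disconnected


def strength(W: np.ndarray) -> float:
    """Network strength: mean over nodes of summed incident weights."""
    W = _weight_matrix(W)
    return float(W.sum() / W.shape[0])


def clustering_and_local_efficiency(
        W: np.ndarray, weight_to_length: str = "reciprocal") -> tuple[float, float]:
    """(C_net, E_local); nodes with fewer than 2 neighbors contribute 0."""
    W = _weight_matrix(W)
    K = W.shape[0]
    W3 = np.cbrt(W)
    triples = np.diag(W3 @ W3 @ W3)          # 2 * sum_{j<k} (w w w)^{1/3}
    k = (W > 0).sum(axis=1)
    C = np.zeros(K)
    E_loc = np.zeros(K)
    for i in range(K):
        if k[i] < 2:
            continue
        C[i] = triples[i] / (k[i] * (k[i] - 1))
        nbrs = np.flatnonzero(W[i] > 0)
        sub = W[np.ix_(nbrs, nbrs)]
        _, eff, _ = path_metrics(sub, weight_to_length)
        E_loc[i] = eff
    return float(C.mean()), float(E_loc.mean())


def compute_metrics(W: np.ndarray,
                    weight_to_length: str = "reciprocal") -> GraphMetricSet:
    W = _weight_matrix(W)
    if not (W > 0).any():
        return GraphMetricSet(L_net=float("inf"), S=0.0, E_global=0.0,
                              E_local=0.0, C_net=0.0,
                              has_disconnected_pairs=True)
    L_net, E_global, disc = path_metrics(W, weight_to_length)
    C_net, E_local = clustering_and_local_efficiency(W, weight_to_length)
    return GraphMetricSet(L_net=L_net, S=strength(W), E_global=E_global,
                          E_local=E_local, C_net=C_net,
                          has_disconnected_pairs=disc)


def per_subject_metrics(matrices: Sequence[ConnectivityMatrix],
                        subject_ids: Sequence[str],
                        subnetwork: Subnetwork | None = None,
                        network: str = "whole_brain",
                        weight_to_length: str = "reciprocal") -> pd.DataFrame:
    rows = []
    for sid, mat in zip(subject_ids, matrices):
        W = whole_brain_graph(mat) if subnetwork is None \
            else subnetwork_graph(mat, subnetwork)
        ms = compute_metrics(W, weight_to_length)
        rows.append({"subject_id": sid, "network": network, **ms.as_dict()})
    return pd.DataFrame(rows)


def stack_matrices(stack: CohortStack) -> list[ConnectivityMatrix]:
    """Rebuild per-subject connectivity matrices from a cohort stack."""
    emap = stack.edge_map
    return [ConnectivityMatrix(values=emap.devectorize(row, diagonal=1.0),
                               node_names=stack.node_names)
            for row in stack.X]


def group_graph_comparison(stack: CohortStack,
                           subnetworks: dict[str, Subnetwork | None],
                           alpha: float = 0.05,
                           weight_to_length: str = "reciprocal") -> pd.DataFrame:
    """Per network x metric: group means, pooled t-test, Cohen's d.

    ``subnetworks`` maps a network name to a Subnetwork, or to None for the
    whole-brain graph.
    """
    matrices = stack_matrices(stack)
    hc = stack.labels == "HC"
    sz = stack.labels == "SZ"
    rows = []
    for name, sn in subnetworks.items():
        df = per_subject_metrics(matrices, stack.subject_ids, sn, name,
                                 weight_to_length)
        for metric in METRIC_NAMES:
            v = df[metric].to_numpy(dtype=float)
            if not np.isfinite(v).all():
                rows.append({"network": name, "metric": metric,
                             "mean_hc": np.nan, "sd_hc": np.nan,
                             "mean_sz": np.nan, "sd_sz": np.nan,
                             "t": np.nan, "p": np.nan, "cohens_d": np.nan,
                             "significant": False})
                continue
            res = ttest_and_effect(v[hc], v[sz], alpha=alpha)
            rows.append({"network": name, "metric": metric,
                         "mean_hc": float(v[hc].mean()),
                         "sd_hc": float(v[hc].std(ddof=1)),
                         "mean_sz": float(v[sz].mean()),
                         "sd_sz": float(v[sz].std(ddof=1)),
                         "t": res.t, "p": res.p, "cohens_d": res.cohens_d,
                         "significant": res.significant})
    return pd.DataFrame(rows)
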