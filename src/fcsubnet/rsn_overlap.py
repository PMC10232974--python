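"""Anatomical distribution of subnetworks and overlap with resting-state
networks (RSNs).

A subnetwork's nodal strength is the sum of absolute ICA values of its
retained edges incident to each node.  Overlap with each of the seven
canonical RSNs (visual, somatomotor, dorsal/ventral attention, limbic,
frontoparietal, default mode) is the percentage of total nodal strength
falling on that RSN's nodes; unlabeled (subcortical) nodes are excluded from
the denominator, so the seven percentages sum to 100.

Significance comes from a permutation null: the retained edge weights are
relocated to a uniformly random edge subset of the same size over all
possible edge positions (default), or shuffled within the retained mask
(``mode="within_mask"``), and the overlap recomputed; the p-value is the
fraction of permutations reaching the observed overlap.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .fc_io import RSN_NAMES, EdgeIndexMap
from .pruning import Subnetwork


def nodal_strength(subnetwork: Subnetwork, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-node sum of |ICA values| of incident retained edges.

    Returns (strength, normalized strength); normalization divides by the
    maximum so the strongest node reads 1 (all-zero map if the subnetwork is
    empty, with a warning).
    """
    emap = EdgeIndexMap(K)
    w = np.abs(subnetwork.ica_values)
    strength = np.zeros(K)
    np.add.at(strength, emap.rows, w)
    np.add.at(strength, emap.cols, w)
    mx = strength.max()
    if mx == 0:
        warnings.warn("empty subnetwork: all nodal strengths zero",
                      RuntimeWarning, stacklevel=2)
        return strength, strength.copy()
    return strength, strength / mx


def _overlap_from_strength(strength: np.ndarray,
                           rsn_labels: np.ndarray) -> np.ndarray:
    labeled = rsn_labels != "None"
    denom = strength[labeled].sum()
    out = np.zeros(len(RSN_NAMES))
    if denom == 0:
        return np.full(len(RSN_NAMES), np.nan)
    for r, name in enumerate(RSN_NAMES):
        out[r] = 100.0 * strength[rsn_labels == name].sum() / denom
    return out


def overlap_percentage(subnetwork: Subnetwork,
                       rsn_labels: Sequence[str]) -> pd.Series:
    """Percentage of (unnormalized) nodal strength on each of the 7 RSNs."""
    labels = np.asarray(rsn_labels, dtype=object)
    K = labels.size
    strength, _ = nodal_strength(subnetwork, K)
    if strength.sum() > 0 and strength[labels != "None"].sum() == 0:
        warnings.warn("all nodal strength sits on unlabeled nodes; "
                      "overlap undefined", RuntimeWarning, stacklevel=2)
    return pd.Series(_overlap_from_strength(strength, labels), index=RSN_NAMES)


def permutation_overlap_test(subnetwork: Subnetwork,
                             rsn_labels: Sequence[str],
                             n_perm: int = 1000,
                             seed: int = 0,
                             mode: str = "relocate",
                             plus_one: bool = False) -> pd.Series:
    """Per-RSN permutation p-values for the observed overlap percentages.

    ``relocate`` reassigns the retained weights to random edge positions over
    all E edges; ``within_mask`` only shuffles the weights among the retained
    positions (a far weaker null that preserves nodal membership).  With
    ``plus_one`` the small-sample-corrected estimator (k+1)/(n+1) is used.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("relocate", "within_mask"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    labels = np.asarray(rsn_labels, dtype=object)
    K = labels.size
    emap = EdgeIndexMap(K)
    observed = overlap_percentage(subnetwork, labels).to_numpy()
    weights = np.abs(subnetwork.ica_values[subnetwork.edge_mask])
    m = weights.size
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    exceed = np.zeros(len(RSN_NAMES))
    valid = 0
    mask_pos = np.flatnonzero(subnetwork.edge_mask)
    for _ in range(n_perm):
        strength = np.zeros(K)
        if m:
            if mode == "relocate":
                pos = rng.choice(emap.E, size=m, replace=False)
                w = weights
            else:
                pos = mask_pos
                w = rng.permutation(weights)
            np.add.at(strength, emap.rows[pos], w)
            np.add.at(strength, emap.cols[pos], w)
        perm = _overlap_from_strength(strength, labels)
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(perm), 0.0, perm >= observed)
        valid += 1
    if plus_one:
        p = (exceed + 1.0) / (valid + 1.0)
    else:
        p = exceed / valid
    return pd.Series(p, index=RSN_NAMES)


def overlap_table(subnetworks: list[Subnetwork],
                  rsn_labels: Sequence[str],
                  n_perm: int = 1000,
                  seed: int = 0,
                  alpha: float = 0.005) -> pd.DataFrame:
    """Overlap percentages and permutation p-values for each subnetwork."""
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(subnetworks)) % (2 ** 31)
    for rank, (sn, s) in enumerate(zip(subnetworks, seeds), start=1):
        pct = overlap_percentage(sn, rsn_labels)
        pvals = permutation_overlap_test(sn, rsn_labels, n_perm=n_perm,
                                         seed=int(s))
        for name in RSN_NAMES:
            rows.append({"subnetwork": rank, "rsn": name,
                         "overlap_pct": pct[name], "p": pvals[name],
                         "significant": bool(pvals[name] < alpha)})
    return pd.DataFrame(rows)
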