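"""Group comparison of subnetworks: projections, t-tests, effect sizes.

Two projections score each subject on a subnetwork:

* Method A uses only the *location* of the retained edges.  The subject's FC
  values at those edges are projected (inner product) onto the absolute
  difference of the HC and SZ group-mean vectors over the same edges.  Note
  the acknowledged circularity: the group means come from the same subjects
  that are scored.
* Method B uses the ICA values themselves: the subject's full edge vector is
  projected onto the pruned, zero-filled ICA-value vector.

Group differences are tested with a pooled-variance two-sample t-test at
alpha = 0.005 and quantified with Cohen's d (pooled SD).  Discriminant links
are the retained edges with |ICA value| above a cut (default 3.5 on the
unit-variance source scale) whose raw FC differs between groups at p < 0.01.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fc_io import CohortStack
from .pruning import Subnetwork


class ProjectionError(ValueError):
    pass


@dataclasses.dataclass
class ProjectionResult:
    method: str                   # "A" or "B"
    scores: np.ndarray            # length N, subject order of the stack
    diff: np.ndarray | None = None  # method A only: |V_HC - V_SZ| on the mask


@dataclasses.dataclass
class StatResult:
    t: float
    p: float
    cohens_d: float
    significant: bool
    alpha: float


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def project_method_A(subnetwork: Subnetwork, stack: CohortStack) -> ProjectionResult:
    mask = subnetwork.edge_mask
    if not mask.any():
        raise ProjectionError("method A needs a non-empty subnetwork")
    hc = stack.X[stack.labels == "HC"][:, mask]
    sz = stack.X[stack.labels == "SZ"][:, mask]
    if hc.size == 0 or sz.size == 0:
        raise ProjectionError("method A needs both groups present")
    diff = np.abs(hc.mean(axis=0) - sz.mean(axis=0))
    scores = stack.X[:, mask] @ diff
    return ProjectionResult(method="A", scores=scores, diff=diff)


def project_method_B(subnetwork: Subnetwork, stack: CohortStack) -> ProjectionResult:
    scores = stack.X @ subnetwork.ica_values
    return ProjectionResult(method="B", scores=scores)


def ttest_and_effect(scores_hc: np.ndarray, scores_sz: np.ndarray,
                     alpha: float = 0.005, equal_var: bool = True) -> StatResult:
    """Two-sample t-test (Student pooled-variance by default) plus Cohen's d."""
    a = np.asarray(scores_hc, float)
    b = np.asarray(scores_sz, float)
    if a.size < 2 or b.size < 2:
        raise ProjectionError("each group needs at least 2 subjects")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult(t=0.0, p=1.0, cohens_d=0.0,
                              significant=False, alpha=alpha)
        raise ProjectionError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(t=float(t), p=float(p), cohens_d=cohens_d(a, b),
                      significant=bool(p < alpha), alpha=alpha)


def subnetwork_stat_table(subnetworks: list[Subnetwork], stack: CohortStack,
                          alpha: float = 0.005) -> pd.DataFrame:
    """Per subnetwork x method: t, p, Cohen's d, significance flag."""
    hc = stack.labels == "HC"
    sz = stack.labels == "SZ"
    rows = []
    for rank, sn in enumerate(subnetworks, start=1):
        for method, project in (("A", project_method_A), ("B", project_method_B)):
            try:
                proj = project(sn, stack)
            except ProjectionError as exc:
                warnings.warn(f"subnetwork {rank} method {method}: {exc}",
                              RuntimeWarning, stacklevel=2)
                continue
            res = ttest_and_effect(proj.scores[hc], proj.scores[sz], alpha=alpha)
            rows.append({
                "subnetwork": rank, "method": method,
                "mean_hc": float(proj.scores[hc].mean()),
                "sd_hc": float(proj.scores[hc].std(ddof=1)),
                "mean_sz": float(proj.scores[sz].mean()),
                "sd_sz": float(proj.scores[sz].std(ddof=1)),
                "t": res.t, "p": res.p, "cohens_d": res.cohens_d,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


def discriminant_links(subnetwork: Subnetwork, stack: CohortStack,
                       ica_cut: float = 3.5, p_cut: float = 0.01) -> pd.DataFrame:
    """Retained edges with |ICA| > ica_cut whose raw FC separates the groups.

    For each surviving edge a pooled-variance t-test compares the original FC
    values between HC and SZ; edges with p < p_cut are returned sorted by p.
    """
    strong = np.flatnonzero(np.abs(subnetwork.ica_values) > ica_cut)
    if strong.size == 0:
        warnings.warn("no edge exceeds the ICA-value cut", RuntimeWarning,
                      stacklevel=2)
        return pd.DataFrame(columns=["edge_index", "node_i", "node_j",
                                     "ica_value", "t", "p"])
    emap = stack.edge_map
    hc = stack.X[stack.labels == "HC"]
    sz = stack.X[stack.labels == "SZ"]
    t, p = stats.ttest_ind(hc[:, strong], sz[:, strong], axis=0, equal_var=True)
    df = pd.DataFrame({
        "edge_index": strong,
        "node_i": [stack.node_names[emap.rows[e]] for e in strong],
        "node_j": [stack.node_names[emap.cols[e]] for e in strong],
        "ica_value": subnetwork.ica_values[strong],
        "t": t, "p": p,
    })
    return df[df["p"] < p_cut].sort_values("p").reset_index(drop=True)
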