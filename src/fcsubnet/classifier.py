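"""Subject scoring and classification from SZ-specific subnetworks.

Each subject's method-B projection onto each selected subnetwork is turned
into two z-scores, one against the HC training distribution and one against
the SZ training distribution.  The per-subnetwork score
``s_i = |z_HC| - |z_SZ|`` is positive when the subject sits closer (in z
units) to the SZ distribution; the total score sums over subnetworks, and
the subject is labeled HC iff the total is strictly negative.

Evaluation reports the confusion-matrix rates, prevalence-adjusted PPV/NPV,
and the Mann-Whitney AUC, plus repeated stratified k-fold cross-validation
in which only the group means/SDs are refit per training fold (the
subnetworks themselves stay fixed, which reproduces the method's
acknowledged residual leakage).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd


class FitError(ValueError):
    pass


METRIC_KEYS = ("accuracy", "balanced_accuracy", "precision", "sensitivity",
               "specificity", "ppv", "npv", "auc")


@dataclasses.dataclass
class ScoreModel:
    """Per-subnetwork group moments of the method-B projections."""

    mu_hc: np.ndarray
    sd_hc: np.ndarray
    mu_sz: np.ndarray
    sd_sz: np.ndarray

    @property
    def n_subnetworks(self) -> int:
        return self.mu_hc.size


@dataclasses.dataclass
class PerformanceMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    balanced_accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    prevalence: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def fit_score_model(projections: np.ndarray, labels: np.ndarray) -> ScoreModel:
    """Fit group means/SDs per subnetwork on training subjects.

    ``projections``: N x M matrix of method-B scores (M subnetworks).
    """
    P = np.atleast_2d(np.asarray(projections, float))
    labels = np.asarray(labels)
    hc = P[labels == "HC"]
    sz = P[labels == "SZ"]
    if hc.shape[0] < 2 or sz.shape[0] < 2:
        raise FitError("need at least 2 training subjects per group")
    sd_hc = hc.std(axis=0, ddof=1)
    sd_sz = sz.std(axis=0, ddof=1)
    if np.any(sd_hc == 0) or np.any(sd_sz == 0):
        raise FitError("zero variance in a training group")
    return ScoreModel(mu_hc=hc.mean(axis=0), sd_hc=sd_hc,
                      mu_sz=sz.mean(axis=0), sd_sz=sd_sz)


def score_subjects(model: ScoreModel, projections: np.ndarray) -> np.ndarray:
    """Total score per subject: sum_i |z_HC,i| - |z_SZ,i| (positive => SZ)."""
    P = np.atleast_2d(np.asarray(projections, float))
    z_hc = np.abs((P - model.mu_hc) / model.sd_hc)
    z_sz = np.abs((P - model.mu_sz) / model.sd_sz)
    return (z_hc - z_sz).sum(axis=1)


def classify(scores: np.ndarray) -> np.ndarray:
    """HC iff score < 0, SZ otherwise (boundary labeled SZ)."""
    return np.where(np.asarray(scores, float) < 0, "HC", "SZ")


def mann_whitney_auc(scores_sz: np.ndarray, scores_hc: np.ndarray) -> float:
    """P(random SZ score > random HC score), ties counted 1/2."""
    a = np.asarray(scores_sz, float)[:, None]
    b = np.asarray(scores_hc, float)[None, :]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / (a.size * b.size / 1))


def ppv_npv(sensitivity: float, specificity: float,
            prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted positive/negative predictive values."""
    pos = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    neg = (1 - sensitivity) * prevalence + specificity * (1 - prevalence)
    ppv = sensitivity * prevalence / pos if pos > 0 else np.nan
    npv = specificity * (1 - prevalence) / neg if neg > 0 else np.nan
    return ppv, npv


def evaluate(scores: np.ndarray, labels: np.ndarray,
             prevalence: float = 0.5) -> PerformanceMetrics:
    """Confusion metrics at threshold 0 (SZ positive) plus AUC and PPV/NPV."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if not (np.any(labels == "HC") and np.any(labels == "SZ")):
        warnings.warn("one-class evaluation: rates undefined", RuntimeWarning,
                      stacklevel=2)
    pred = classify(scores)
    TP = int(np.sum((pred == "SZ") & (labels == "SZ")))
    TN = int(np.sum((pred == "HC") & (labels == "HC")))
    FP = int(np.sum((pred == "SZ") & (labels == "HC")))
    FN = int(np.sum((pred == "HC") & (labels == "SZ")))
    n = TP + TN + FP + FN
    acc = (TP + TN) / n if n else np.nan
    sens = TP / (TP + FN) if TP + FN else np.nan
    spec = TN / (TN + FP) if TN + FP else np.nan
    prec = TP / (TP + FP) if TP + FP else np.nan
    bal = (sens + spec) / 2
    ppv, npv = ppv_npv(sens, spec, prevalence)
    auc = mann_whitney_auc(scores[labels == "SZ"], scores[labels == "HC"]) \
        if (labels == "SZ").any() and (labels == "HC").any() else np.nan
    return PerformanceMetrics(TP=TP, TN=TN, FP=FP, FN=FN, accuracy=acc,
                              balanced_accuracy=bal, precision=prec,
                              sensitivity=sens, specificity=spec,
                              ppv=ppv, npv=npv, auc=auc, prevalence=prevalence)


def _stratified_folds(labels: np.ndarray, k: int,
                      rng: np.random.Generator,
                      stratified: bool) -> list[np.ndarray]:
    N = labels.size
    if stratified:
        folds: list[list[int]] = [[] for _ in range(k)]
        for group in ("HC", "SZ"):
            idx = rng.permutation(np.flatnonzero(labels == group))
            for pos, i in enumerate(idx):
                folds[pos % k].append(int(i))
        return [np.array(sorted(f)) for f in folds]
    idx = rng.permutation(N)
    return [np.array(sorted(f)) for f in np.array_split(idx, k)]


def cross_validate(projections: np.ndarray, labels: np.ndarray,
                   k: int = 6, repeats: int = 10, seed: int = 0,
                   prevalence: float = 0.5,
                   stratified: bool = True) -> tuple[dict[str, float], pd.DataFrame]:
    """Repeated k-fold CV; returns (per-metric means, per-fold table).

    Per fold the score model (group moments) is refit on the training
    subjects only; the projections (and hence the subnetworks) are fixed
    inputs.  Folds missing a class are skipped with a warning.
    """
    P = np.atleast_2d(np.asarray(projections, float))
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for rep in range(repeats):
        folds = _stratified_folds(labels, k, rng, stratified)
        for fi, test_idx in enumerate(folds):
            train = np.ones(labels.size, bool)
            train[test_idx] = False
            y_test = labels[test_idx]
            if not (np.any(y_test == "HC") and np.any(y_test == "SZ")):
                warnings.warn(f"repeat {rep} fold {fi}: single-class test "
                              f"fold skipped", RuntimeWarning, stacklevel=2)
                continue
            model = fit_score_model(P[train], labels[train])
            scores = score_subjects(model, P[test_idx])
            m = evaluate(scores, y_test, prevalence=prevalence)
            rows.append({"repeat": rep, "fold": fi,
                         **{key: getattr(m, key) for key in METRIC_KEYS}})
    folds_df = pd.DataFrame(rows)
    means = {key: float(folds_df[key].mean()) for key in METRIC_KEYS} \
        if len(folds_df) else {key: np.nan for key in METRIC_KEYS}
    return means, folds_df


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve from sweeping a threshold over the continuous total score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    thresholds = np.concatenate(([np.inf], np.sort(np.unique(scores))[::-1],
                                 [-np.inf]))
    n_sz = (labels == "SZ").sum()
    n_hc = (labels == "HC").sum()
    rows = []
    for thr in thresholds:
        pred_sz = scores >= thr
        tpr = (pred_sz & (labels == "SZ")).sum() / n_sz if n_sz else np.nan
        fpr = (pred_sz & (labels == "HC")).sum() / n_hc if n_hc else np.nan
        rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)
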