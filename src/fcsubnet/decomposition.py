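"""Subject-dimension PCA, Infomax ICA and reproducibility ranking.

The cohort matrix ``X`` (subjects x edges) is reduced along the *subject*
dimension with PCA, keeping the smallest number of components ``C`` whose
cumulative explained variance reaches the retention target (default 90%).
The reduced matrix ``X'`` (``C x E``) is then decomposed as ``X' = A @ S``
by Infomax ICA (natural-gradient ascent with a logistic nonlinearity); each
row of ``S`` is a component whose entries are the "ICA values" of the edges.

Because ICA orderings and signs vary run to run, the decomposition is
repeated with different random initializations and the runs are aligned by a
modified RAICAR procedure: components of a canonical reference run are
matched to every other run by absolute Pearson correlation over the edges,
and ranked by a reproducibility score that combines the number of matching
runs with the mean matched correlation.  The representative component is the
reference run's own row — never an average — so repeated executions return
the same edge values.

Conventions frozen here and relied on downstream: rows of ``S`` have unit
variance (so ICA-value thresholds such as 3.5 read as z-scores), and each
row's largest-magnitude entry is positive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .fc_io import CohortStack


class DecompositionError(ValueError):
    pass


@dataclasses.dataclass
class ReducedFeatures:
    """PCA-reduced cohort: X' = projector @ X_centered, C x E."""

    Xprime: np.ndarray
    projector: np.ndarray         # C x N
    explained_variance: float     # cumulative fraction at C
    singular_values: np.ndarray
    column_means: np.ndarray      # per-edge means removed before projection

    @property
    def C(self) -> int:
        return self.Xprime.shape[0]


@dataclasses.dataclass
class Decomposition:
    """One ICA run: A @ S == X' exactly (invertible linear maps throughout)."""

    A: np.ndarray                 # C x C mixing
    S: np.ndarray                 # C x E sources, unit-variance rows
    run_seed: int
    converged: bool
    n_iter: int


@dataclasses.dataclass
class ComponentRecord:
    s_row: np.ndarray
    a_col: np.ndarray
    reproducibility: float
    match_count: int
    mean_abs_corr: float
    source_index: int             # index within the reference run


@dataclasses.dataclass
class RankedComponents:
    components: list[ComponentRecord]
    reference_run: int
    n_runs: int
    match_threshold: float

    def __len__(self) -> int:
        return len(self.components)

    @property
    def S(self) -> np.ndarray:
        return np.stack([c.s_row for c in self.components])

    @property
    def A(self) -> np.ndarray:
        return np.stack([c.a_col for c in self.components], axis=1)


def _fix_row_signs(S: np.ndarray, A: np.ndarray | None = None):
    """Flip each source row so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(S), axis=1)
    signs = np.sign(S[np.arange(S.shape[0]), idx])
    signs[signs == 0] = 1.0
    S = S * signs[:, None]
    if A is not None:
        A = A * signs[None, :]
    return S, A


def pca_reduce(stack: CohortStack | np.ndarray,
               variance_target: float = 0.90) -> ReducedFeatures:
    """Reduce the subject dimension, keeping >= ``variance_target`` variance.

    Columns (edges) are mean-centered across subjects; the SVD sign is
    canonicalized on the edge-space singular vectors, which makes ``X'``
    invariant under permutations of the input subjects.
    """
    X = stack.X if isinstance(stack, CohortStack) else np.asarray(stack, float)
    N = X.shape[0]
    if N < 3:
        raise DecompositionError("PCA along subjects needs N >= 3")
    if not (0.0 < variance_target <= 1.0):
        raise DecompositionError("variance_target must lie in (0, 1]")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise DecompositionError("cohort has zero variance after centering")
    cum = np.cumsum(var) / total
    C = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    C = min(C, int(np.sum(s > s[0] * 1e-12)))  # drop numerically null dims
    if C < 1:
        raise DecompositionError("rank-deficient cohort: no component retained")
    # sign convention on edge-space directions: largest |entry| positive
    Vt_C = Vt[:C]
    idx = np.argmax(np.abs(Vt_C), axis=1)
    signs = np.sign(Vt_C[np.arange(C), idx])
    signs[signs == 0] = 1.0
    Xprime = (signs * s[:C])[:, None] * Vt_C          # = signed Sigma V^T
    # quantize to a fixed relative grid: subject-order permutations perturb
    # the SVD at ~1e-14, which the (chaotic) ICA iteration would otherwise
    # amplify; on the grid the ICA input is bit-identical for any ordering
    q = np.max(np.abs(Xprime)) * 1e-6
    if q > 0:
        q = float(2.0 ** np.ceil(np.log2(q)))  # power-of-two grid: exact scale
        Xprime = np.round(Xprime / q) * q
    projector = signs[:, None] * U[:, :C].T           # C x N
    return ReducedFeatures(
        Xprime=Xprime,
        projector=projector,
        explained_variance=float(cum[C - 1]),
        singular_values=s[:C].copy(),
        column_means=mu,
    )


def infomax_ica(reduced: ReducedFeatures | np.ndarray,
                seed: int = 0,
                max_iter: int = 5000,
                tol: float = 1e-7,
                learning_rate: float = 0.1,
                anneal: float = 0.98) -> Decomposition:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    The input is whitened internally (second-moment whitening, so the exact
    identity ``A @ S == X'`` holds).  The unmixing matrix follows the
    classic update ``dW = lr * (I + (1 - 2g(Y)) Y^T / E) W``; the learning
    rate is multiplied by ``anneal`` whenever the update norm grows (damping
    the late oscillation of full-batch updates) and halved outright on
    divergence.  Deterministic given ``seed``; non-convergence within
    ``max_iter`` yields a warning and ``converged=False``, never an
    exception.
    """
    Xp = reduced.Xprime if isinstance(reduced, ReducedFeatures) else np.asarray(reduced, float)
    C, E = Xp.shape
    if C < 2:
        raise DecompositionError("ICA needs at least 2 components")

    # second-moment whitening (no centering, keeps A @ S == X' exact)
    M2 = Xp @ Xp.T / E
    evals, evecs = np.linalg.eigh(M2)
    if evals[0] <= evals[-1] * 1e-12:
        raise DecompositionError("reduced features are rank deficient")
    Wh = (evecs / np.sqrt(evals)).T          # C x C, rows scaled
    Z = Wh @ Xp

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    W, _ = np.linalg.qr(rng.normal(size=(C, C)))
    I = np.eye(C)
    lr = learning_rate
    converged = False
    n_iter = 0
    prev_rel = np.inf
    for n_iter in range(1, max_iter + 1):
        Y = W @ Z
        g = 1.0 / (1.0 + np.exp(-Y))
        grad = I + (1.0 - 2.0 * g) @ Y.T / E
        step = lr * grad @ W
        step_norm = np.linalg.norm(step)
        if not np.isfinite(step_norm) or step_norm > 1e3:
            lr *= 0.5            # diverged: back off hard and retry
            prev_rel = np.inf
            if lr < 1e-12:
                break
            continue
        rel = step_norm / max(np.linalg.norm(W), 1e-300)
        if rel > prev_rel:
            lr *= anneal         # oscillating near the fixed point
        prev_rel = rel
        W = W + step
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Infomax ICA did not converge in {max_iter} iterations "
                      f"(seed {seed})", RuntimeWarning, stacklevel=2)

    M = W @ Wh                              # full unmixing of X'
    S_raw = M @ Xp
    scale = S_raw.std(axis=1)
    scale[scale == 0] = 1.0
    S = S_raw / scale[:, None]
    A = np.linalg.inv(M) * scale[None, :]   # A @ S == X' exactly
    S, A = _fix_row_signs(S, A)
    return Decomposition(A=A, S=S, run_seed=int(seed),
                         converged=converged, n_iter=n_iter)


def run_ica_ensemble(reduced: ReducedFeatures,
                     n_runs: int = 100,
                     seed: int = 0,
                     max_iter: int = 5000,
                     tol: float = 1e-7) -> list[Decomposition]:
    """Repeat Infomax with run seeds derived deterministically from ``seed``."""
    child = np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)
    return [infomax_ica(reduced, seed=int(s), max_iter=max_iter, tol=tol)
            for s in child]


def _abs_corr_matrix(Sa: np.ndarray, Sb: np.ndarray) -> np.ndarray:
    za = Sa - Sa.mean(axis=1, keepdims=True)
    zb = Sb - Sb.mean(axis=1, keepdims=True)
    za /= np.linalg.norm(za, axis=1, keepdims=True)
    zb /= np.linalg.norm(zb, axis=1, keepdims=True)
    return np.abs(za @ zb.T)


def raicar_align(runs: list[Decomposition],
                 match_threshold: float = 0.8) -> RankedComponents:
    """Align repeated ICA runs and rank components by reproducibility.

    For each component of the reference run, its best partner in every other
    run is found by absolute Pearson correlation over the edges.
    ``match_count`` counts runs whose best partner reaches
    ``match_threshold``; the reproducibility score is
    ``(match_count / (R - 1)) * mean_abs_corr`` with the mean taken over the
    matched runs.  The reference run is the one whose components achieve the
    highest total best-partner correlation over all other runs (the most
    central run), so the output carries genuine, unaveraged ICA values.
    """
    R = len(runs)
    if R < 2:
        raise DecompositionError("RAICAR alignment needs at least 2 runs")
    C = runs[0].S.shape[0]
    for r in runs:
        if r.S.shape[0] != C:
            raise DecompositionError("all runs must share the component count")

    best = np.zeros((R, R, C))   # best[r, q, c]: run r comp c vs best of run q
    for r in range(R):
        for q in range(r + 1, R):
            cc = _abs_corr_matrix(runs[r].S, runs[q].S)
            best[r, q] = cc.max(axis=1)
            best[q, r] = cc.max(axis=0)

    totals = best.sum(axis=(1, 2))
    ref = int(np.argmax(totals))

    records = []
    for c in range(C):
        partners = np.array([best[ref, q, c] for q in range(R) if q != ref])
        matched = partners >= match_threshold
        match_count = int(matched.sum())
        mean_abs = float(partners[matched].mean()) if match_count else 0.0
        score = (match_count / (R - 1)) * mean_abs
        s_row, a_col = runs[ref].S[c].copy(), runs[ref].A[:, c].copy()
        s_fixed, a_fixed = _fix_row_signs(s_row[None, :], a_col[:, None])
        records.append(ComponentRecord(
            s_row=s_fixed[0], a_col=a_fixed[:, 0],
            reproducibility=float(score), match_count=match_count,
            mean_abs_corr=mean_abs, source_index=c))

    records.sort(key=lambda rec: (-rec.reproducibility, -rec.mean_abs_corr,
                                  rec.source_index))
    return RankedComponents(components=records, reference_run=ref,
                            n_runs=R, match_threshold=match_threshold)


def select_components(ranked: RankedComponents, n: int = 8) -> RankedComponents:
    """Keep the n highest-ranked components."""
    if n > len(ranked):
        raise DecompositionError(f"cannot select {n} of {len(ranked)} components")
    return RankedComponents(components=ranked.components[:n],
                            reference_run=ranked.reference_run,
                            n_runs=ranked.n_runs,
                            match_threshold=ranked.match_threshold)


def decompose(stack: CohortStack,
              variance_target: float = 0.90,
              n_runs: int = 100,
              seed: int = 0,
              match_threshold: float = 0.8,
              n_select: int | None = 8,
              max_iter: int = 5000,
              tol: float = 1e-7) -> tuple[ReducedFeatures, RankedComponents]:
    """PCA -> repeated Infomax -> RAICAR ranking -> top-n selection."""
    reduced = pca_reduce(stack, variance_target)
    runs = run_ica_ensemble(reduced, n_runs=n_runs, seed=seed,
                            max_iter=max_iter, tol=tol)
    ranked = raicar_align(runs, match_threshold=match_threshold)
    if n_select is not None:
        ranked = select_components(ranked, min(n_select, len(ranked)))
    return reduced, ranked
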