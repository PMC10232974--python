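"""Reading, validation and vectorization of functional-connectivity matrices.

A subject's functional connectivity (FC) is a symmetric ``K x K`` matrix of
Pearson correlations between regional fMRI time courses.  All downstream
analysis works on the vectorized lower triangle of the *absolute* correlations,
stacked across subjects into an ``N x E`` cohort matrix with
``E = K(K-1)/2`` edges.

The edge order is frozen: lower triangle, row-major (node index ``i``
ascending, then ``j < i`` ascending).  This is the order produced by
``numpy.tril_indices(K, -1)`` and is used for every on-disk edge vector.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("HC", "SZ")
RSN_NAMES = ("Vis", "SM", "DA", "VA", "Limb", "FP", "DMN")
RSN_LABELS_ALLOWED = RSN_NAMES + ("None",)

SYMMETRY_TOL = 1e-8


class FormatError(ValueError):
    """Input file is not a readable square numeric matrix."""


class ValidationError(ValueError):
    """Matrix violates a structural invariant (symmetry, range, labels)."""


@dataclasses.dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's K x K symmetric FC matrix (Pearson r, dimensionless)."""

    values: np.ndarray
    node_names: tuple[str, ...]

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got {v.shape}")
        if len(self.node_names) != v.shape[0]:
            raise ValidationError("node_names length must equal K")
        if not np.array_equal(v, v.T):
            raise ValidationError("matrix is not exactly symmetric after load")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.min(off) < -1.0 or np.max(off) > 1.0):
            raise ValidationError("off-diagonal entries must lie in [-1, 1]")


class EdgeIndexMap:
    """Fixed bijection between node pairs (i, j), i > j, and linear edge index.

    Order is row-major over the lower triangle: ``(1,0), (2,0), (2,1), ...``.
    """

    def __init__(self, K: int):
        if K < 2:
            raise ValidationError("edge indexing needs K >= 2")
        self.K = int(K)
        self.rows, self.cols = np.tril_indices(K, -1)
        self.E = self.rows.size  # == K(K-1)/2

    def edge_names(self, node_names: Sequence[str]) -> list[str]:
        return [f"{node_names[i]}|{node_names[j]}"
                for i, j in zip(self.rows, self.cols)]

    def vectorize(self, matrix: np.ndarray) -> np.ndarray:
        """Lower-triangle entries in canonical order (no absolute value)."""
        return np.asarray(matrix)[self.rows, self.cols]

    def devectorize(self, vec: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.E,):
            raise ValidationError(f"edge vector must have length {self.E}")
        M = np.full((self.K, self.K), float(diagonal))
        M[self.rows, self.cols] = vec
        M[self.cols, self.rows] = vec
        return M


@dataclasses.dataclass
class CohortStack:
    """Cohort matrix X: one row per subject, absolute FC per edge in [0, 1]."""

    X: np.ndarray
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    node_names: tuple[str, ...]

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def E(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return len(self.node_names)

    @property
    def edge_map(self) -> EdgeIndexMap:
        return EdgeIndexMap(self.K)

    def group_rows(self, group: str) -> np.ndarray:
        return self.X[self.labels == group]


def read_fc_matrix(path: str | Path, expected_K: int | None = None) -> ConnectivityMatrix:
    """Read a delimited (CSV/TSV/whitespace) numeric K x K matrix.

    Asymmetry up to 1e-8 is repaired by averaging with the transpose;
    larger asymmetry is an error.
    """
    path = Path(path)
    rows: list[list[float]] = []
    try:
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "\t" in line:
                    tokens = line.split("\t")
                elif "," in line:
                    tokens = line.split(",")
                else:
                    tokens = line.split()
                # float() round-trips shortest reprs exactly, unlike the
                # pandas csv float parsers
                rows.append([float(t) for t in tokens])
        values = np.array(rows, dtype=float)
    except (OSError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as a numeric matrix: {exc}") from exc
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"{path}: matrix is not square (shape {values.shape})")
    K = values.shape[0]
    if expected_K is not None and K != expected_K:
        raise ValidationError(f"{path}: expected K={expected_K}, found K={K}")
    asym = np.max(np.abs(values - values.T)) if K else 0.0
    if asym > SYMMETRY_TOL:
        raise ValidationError(f"{path}: asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL}")
    values = (values + values.T) / 2.0
    off = values[~np.eye(K, dtype=bool)]
    if off.size and (off.min() < -1.0 or off.max() > 1.0):
        raise ValidationError(f"{path}: correlation entries outside [-1, 1]")
    names = tuple(f"n{idx:03d}" for idx in range(K))
    return ConnectivityMatrix(values=values, node_names=names)


def vectorize_lower(matrix: ConnectivityMatrix) -> np.ndarray:
    """Absolute lower-triangle edge vector in canonical order."""
    emap = EdgeIndexMap(matrix.K)
    return np.abs(emap.vectorize(matrix.values))


def stack_cohort(
    matrices: Sequence[ConnectivityMatrix],
    labels: Sequence[str],
    subject_ids: Sequence[str] | None = None,
) -> CohortStack:
    if not matrices:
        raise ValidationError("cohort is empty")
    if len(matrices) != len(labels):
        raise ValidationError("one label per matrix required")
    K = matrices[0].K
    names = matrices[0].node_names
    for m in matrices:
        if m.K != K:
            raise ValidationError(f"mixed parcellations: K={m.K} vs K={K}")
    for lab in labels:
        if lab not in GROUPS:
            raise ValidationError(f"unknown group label {lab!r}; expected one of {GROUPS}")
    if subject_ids is None:
        subject_ids = tuple(f"sub-{i:03d}" for i in range(len(matrices)))
    X = np.stack([vectorize_lower(m) for m in matrices])
    return CohortStack(
        X=X,
        labels=np.asarray(labels, dtype=object),
        subject_ids=tuple(subject_ids),
        node_names=names,
    )


def normality_screen(stack: CohortStack) -> pd.DataFrame:
    """Shapiro-Wilk normality screen of each subject's edge-value vector.

    Purely diagnostic: the pipeline never gates on this.  Constant rows are
    flagged untestable rather than failing.
    """
    records = []
    for sid, row in zip(stack.subject_ids, stack.X):
        if np.ptp(row) == 0.0:
            records.append({"subject_id": sid, "W": np.nan, "p": np.nan,
                            "untestable": True})
            continue
        res = stats.shapiro(row)
        records.append({"subject_id": sid, "W": float(res.statistic),
                        "p": float(res.pvalue), "untestable": False})
    df = pd.DataFrame.from_records(records)
    df.attrs["min_p"] = float(np.nanmin(df["p"])) if df["p"].notna().any() else np.nan
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: subject_id, group in {HC, SZ}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["subject_id", "group"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "group"],
                         dtype=str, keep_default_na=False)
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}")
    return df


def read_rsn_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV: node_name, rsn in {Vis,SM,DA,VA,Limb,FP,DMN,None}.

    ``keep_default_na`` is off so the literal label "None" survives parsing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["node_name", "rsn"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["node_name", "rsn"],
                         dtype=str, keep_default_na=False)
    bad = set(df["rsn"]) - set(RSN_LABELS_ALLOWED)
    if bad:
        raise ValidationError(f"unknown RSN labels {sorted(bad)}")
    return df


def write_stack(stack: CohortStack, path: str | Path) -> None:
    """Edge-vector stack as TSV with 'node_i|node_j' header columns."""
    emap = stack.edge_map
    df = pd.DataFrame(stack.X, columns=emap.edge_names(stack.node_names))
    df.insert(0, "subject_id", stack.subject_ids)
    df.insert(1, "group", stack.labels)
    df.to_csv(path, sep="\t", index=False)
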