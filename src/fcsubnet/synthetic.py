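"""Synthetic two-group FC cohorts with planted subnetwork structure.

The generator emulates the layout of a case/control resting-state study: each
subject contributes a symmetric ``K x K`` matrix of absolute correlations.
The cohort follows the linear mixing model behind the decomposition stage,

    X = L @ S + baseline + noise,   clipped to [0, 1],

where the rows of ``S`` are sparse, spatially blocky edge-space sources
(each concentrated on the edges of a contiguous node block, so the planted
subnetwork is anatomically connected), and ``L`` holds subject loadings drawn
from a Laplace distribution (super-Gaussian, which is what makes the sources
identifiable to an Infomax ICA with a logistic nonlinearity).  Designated
"effect" components carry a group shift: the realized SZ-vs-HC difference of
their loading means is exactly ``effect_size`` loading standard deviations.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fc_io import (
    RSN_NAMES,
    CohortStack,
    ConnectivityMatrix,
    EdgeIndexMap,
    stack_cohort,
)


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for a planted two-group cohort.

    Defaults describe the standard test cohort: 30 nodes, 20 subjects per
    group, four latent components of which the first carries a 1.5-SD group
    shift in its loadings, 10% of edges active per component and additive
    edge noise of SD 0.05 on absolute-correlation units.
    """

    K: int = 30
    n_hc: int = 20
    n_sz: int = 20
    n_components: int = 4
    effect_components: tuple[int, ...] = (0,)
    effect_size: float = 1.5
    noise_sd: float = 0.05
    sparsity: float = 0.10
    loading_sd: float = 0.05
    baseline_range: tuple[float, float] = (0.3, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components > self.n_hc + self.n_sz:
            raise ConfigError("n_components cannot exceed the subject count")
        if not (0.0 < self.sparsity <= 1.0):
            raise ConfigError("sparsity must lie in (0, 1]")
        E = self.K * (self.K - 1) // 2
        if int(round(self.sparsity * E)) < 1:
            raise ConfigError("sparsity leaves zero active edges per component")
        for c in self.effect_components:
            if not (0 <= c < self.n_components):
                raise ConfigError(
                    f"effect component index {c} outside 0..{self.n_components - 1}")


@dataclasses.dataclass
class GroundTruth:
    """Planted sources, loadings and RSN labels of a synthetic cohort."""

    sources: np.ndarray          # n_components x E, unit variance rows
    loadings: np.ndarray         # N x n_components
    rsn_map: pd.DataFrame        # node_name, rsn
    node_blocks: list[np.ndarray]
    config: SyntheticConfig


def _planted_rsn_map(K: int, node_names: Sequence[str],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous RSN chunks over the nodes, last ~10% unlabeled ("None")."""
    n_none = max(1, K // 10)
    n_labeled = K - n_none
    bounds = np.linspace(0, n_labeled, len(RSN_NAMES) + 1).astype(int)
    labels = []
    for r, name in enumerate(RSN_NAMES):
        labels.extend([name] * (bounds[r + 1] - bounds[r]))
    labels.extend(["None"] * n_none)
    return pd.DataFrame({"node_name": list(node_names), "rsn": labels})


def generate_cohort(config: SyntheticConfig) -> tuple[CohortStack, GroundTruth]:
    """Draw one deterministic cohort plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    emap = EdgeIndexMap(cfg.K)
    E = emap.E
    N = cfg.n_hc + cfg.n_sz
    m = int(round(cfg.sparsity * E))

    # block size: smallest contiguous node block with >= m internal edges
    b = 2
    while b * (b - 1) // 2 < m:
        b += 1
    b = min(b, cfg.K)

    sources = np.zeros((cfg.n_components, E))
    node_blocks: list[np.ndarray] = []
    # evenly spaced block starts: components tile the node range with minimal
    # mutual overlap, mimicking spatially segregated functional systems
    if cfg.n_components > 1:
        starts = np.round(np.linspace(0, cfg.K - b, cfg.n_components)).astype(int)
    else:
        starts = np.array([(cfg.K - b) // 2])
    for c in range(cfg.n_components):
        block = np.arange(starts[c], starts[c] + b)
        node_blocks.append(block)
        in_block = np.flatnonzero(
            np.isin(emap.rows, block) & np.isin(emap.cols, block))
        chosen = rng.choice(in_block, size=m, replace=False)
        vals = rng.normal(size=m)
        sources[c, chosen] = vals
        sources[c] /= sources[c].std()  # unit variance over all E entries

    # Laplace loadings: scale = sd / sqrt(2)
    loadings = rng.laplace(loc=0.0, scale=cfg.loading_sd / np.sqrt(2.0),
                           size=(N, cfg.n_components))
    sz = slice(cfg.n_hc, N)
    hc = slice(0, cfg.n_hc)
    for c in cfg.effect_components:
        # realized group-mean gap pinned to effect_size * loading SD
        target = cfg.effect_size * cfg.loading_sd
        gap = loadings[sz, c].mean() - loadings[hc, c].mean()
        loadings[sz, c] += target - gap

    baseline = rng.uniform(*cfg.baseline_range, size=E)
    noise = rng.normal(scale=cfg.noise_sd, size=(N, E)) if cfg.noise_sd > 0 else 0.0
    X = np.clip(loadings @ sources + baseline + noise, 0.0, 1.0)

    node_names = tuple(f"n{idx:03d}" for idx in range(cfg.K))
    matrices = [
        ConnectivityMatrix(values=emap.devectorize(row, diagonal=1.0),
                           node_names=node_names)
        for row in X
    ]
    labels = ["HC"] * cfg.n_hc + ["SZ"] * cfg.n_sz
    ids = [f"hc-{i:03d}" for i in range(cfg.n_hc)] + \
          [f"sz-{i:03d}" for i in range(cfg.n_sz)]
    stack = stack_cohort(matrices, labels, ids)
    truth = GroundTruth(sources=sources, loadings=loadings,
                        rsn_map=_planted_rsn_map(cfg.K, node_names, rng),
                        node_blocks=node_blocks, config=cfg)
    return stack, truth


def _fmt(x: float) -> str:
    return np.format_float_scientific(x, unique=True, trim="-")


def write_fixture_set(stack: CohortStack, truth: GroundTruth,
                      directory: str | Path) -> dict:
    """Write per-subject matrices, label/RSN tables and truth tables.

    Floats are written with round-trip precision so re-reading reproduces the
    cohort matrix bit-exactly; two writes from the same seed are
    byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    emap = stack.edge_map
    matrix_files = []
    for sid, row in zip(stack.subject_ids, stack.X):
        M = emap.devectorize(row, diagonal=1.0)
        fname = f"{sid}.tsv"
        with open(directory / fname, "w") as fh:
            for r in M:
                fh.write("\t".join(_fmt(v) for v in r) + "\n")
        matrix_files.append(fname)

    pd.DataFrame({"subject_id": stack.subject_ids, "group": stack.labels}) \
        .to_csv(directory / "labels.tsv", sep="\t", index=False)
    truth.rsn_map.to_csv(directory / "rsn_map.tsv", sep="\t", index=False)
    np.savetxt(directory / "truth_sources.tsv", truth.sources, delimiter="\t")
    np.savetxt(directory / "truth_loadings.tsv", truth.loadings, delimiter="\t")

    manifest = {
        "seed": truth.config.seed,
        "config": dataclasses.asdict(truth.config),
        "matrices": matrix_files,
        "labels": "labels.tsv",
        "rsn_map": "rsn_map.tsv",
        "truth": ["truth_sources.tsv", "truth_loadings.tsv"],
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
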