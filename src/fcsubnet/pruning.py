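"""Edge pruning: keep each component's most reconstruction-relevant edges.

For the linear model ``X' = A @ S``, zeroing a single source entry
``S[i, e]`` increases the squared reconstruction error of ``X'`` by exactly
``||A[:, i]||^2 * S[i, e]^2``.  That closed form is the per-edge
contribution used here: edges with the largest effect on the reversibility
of the decomposition are kept, the rest are zeroed.  Contributions are
normalized by the global maximum over all components, so the retained edge
count is free to differ between components.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .decomposition import RankedComponents


@dataclasses.dataclass(frozen=True)
class PruningConfig:
    threshold: float = 0.2
    mode: str = "relative_max"    # or "cumulative"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("pruning threshold must lie in (0, 1)")
        if self.mode not in ("relative_max", "cumulative"):
            raise ValueError(f"unknown pruning mode {self.mode!r}")


@dataclasses.dataclass
class Subnetwork:
    """A component restricted to its retained edges (ICA values elsewhere 0)."""

    component_index: int
    edge_mask: np.ndarray         # boolean, length E
    ica_values: np.ndarray        # length E, zero off-mask
    retained_fraction: float
    dropped_contribution: float   # raw squared-error increase from pruning


def edge_contributions(components: RankedComponents) -> np.ndarray:
    """Per-component, per-edge reconstruction contribution, normalized
    by the global maximum (so values lie in [0, 1])."""
    S = components.S
    A = components.A
    raw = (np.linalg.norm(A, axis=0) ** 2)[:, None] * S ** 2
    gmax = raw.max()
    if gmax == 0:
        return raw
    return raw / gmax


def prune(components: RankedComponents,
          config: PruningConfig = PruningConfig()) -> list[Subnetwork]:
    """Apply the pruning rule, returning one Subnetwork per component.

    relative_max: keep edge e of component i iff its normalized contribution
    reaches ``threshold`` (a fraction of the global maximum).
    cumulative: keep, per component, the smallest edge set covering
    ``1 - threshold`` of that component's contribution mass.
    """
    S = components.S
    A = components.A
    raw = (np.linalg.norm(A, axis=0) ** 2)[:, None] * S ** 2
    gmax = raw.max()
    E = S.shape[1]
    subnets: list[Subnetwork] = []
    for i in range(S.shape[0]):
        if config.mode == "relative_max":
            mask = raw[i] >= config.threshold * gmax if gmax > 0 \
                else np.zeros(E, bool)
        else:
            order = np.argsort(raw[i])[::-1]
            csum = np.cumsum(raw[i][order])
            total = csum[-1]
            mask = np.zeros(E, bool)
            if total > 0:
                n_keep = int(np.searchsorted(csum, (1.0 - config.threshold) * total) + 1)
                mask[order[:n_keep]] = True
        if not mask.any():
            warnings.warn(f"component {i}: no edge passes the pruning "
                          f"threshold; empty subnetwork", RuntimeWarning,
                          stacklevel=2)
        vals = np.where(mask, S[i], 0.0)
        subnets.append(Subnetwork(
            component_index=i,
            edge_mask=mask,
            ica_values=vals,
            retained_fraction=float(mask.mean()),
            dropped_contribution=float(raw[i][~mask].sum()),
        ))
    return subnets


def pruning_degradation(subnetworks: list[Subnetwork]) -> float:
    """Total added squared reconstruction error = sum of dropped contributions."""
    return float(sum(s.dropped_contribution for s in subnetworks))
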