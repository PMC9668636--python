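"""Density thresholding of group probability matrices.

Low-probability connections — edges reconstructed in only a small fraction of
subjects, typically tractography false positives — are removed by retaining
the K highest-probability edges, where K = floor(density * n(n-1)/2).  Using a
fixed target density (15% by default) guarantees equal edge counts across
sites, which keeps between-site comparisons of network architecture fair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .connectome import ConnectivityMatrix, upper_triangle_pairs

__all__ = ["ThresholdConfig", "EdgeMask", "density_threshold", "apply_mask"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdConfig:
    """Target edge density (fraction of possible node pairs retained)."""

    density: float = 0.15
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must lie in (0, 1]")
        if self.tie_break != "lexicographic":
            raise ValueError(f"unknown tie_break rule: {self.tie_break!r}")


@dataclass
class EdgeMask:
    """Symmetric binary mask over node pairs; retained_count upper-triangle edges."""

    mask: np.ndarray
    retained_count: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask) != 0):
            raise ValueError("mask diagonal must be zero")
        n = self.mask.shape[0]
        iu = np.triu_indices(n, k=1)
        if int(self.mask[iu].sum()) != self.retained_count:
            raise ValueError("retained_count inconsistent with mask")

    def edge_set(self) -> set[tuple[int, int]]:
        iu = np.triu_indices(self.mask.shape[0], k=1)
        rows, cols = iu[0][self.mask[iu] > 0], iu[1][self.mask[iu] > 0]
        return {(int(i), int(j)) for i, j in zip(rows, cols)}

    def to_tsv(self, path, node_labels=None) -> None:
        ConnectivityMatrix(values=self.mask.astype(float), node_labels=node_labels or []).to_tsv(
            path
        )


def density_threshold(probability: np.ndarray, config: ThresholdConfig | None = None) -> EdgeMask:
    """Retain the K = floor(density * n(n-1)/2) highest-probability edges.

    Ties at the cutoff are broken deterministically in lexicographic node-pair
    order (smaller (i, j) wins).  If fewer than K edges have nonzero
    probability, all nonzero edges are retained and a warning is logged — the
    realized density then falls short of the target.
    """
    config = config or ThresholdConfig()
    probability = np.asarray(probability, dtype=float)
    n = probability.shape[0]
    if probability.shape != (n, n):
        raise ValueError("probability matrix must be square")
    n_pairs = n * (n - 1) // 2
    k = int(np.floor(config.density * n_pairs))
    pairs = upper_triangle_pairs(n)
    probs = np.array([probability[i, j] for i, j in pairs])
    nonzero = int(np.sum(probs > 0))
    if nonzero < k:
        logger.warning(
            "only %d nonzero edges available for target of %d; retaining all nonzero",
            nonzero,
            k,
        )
        k = nonzero
    # stable sort on descending probability keeps lexicographic order among ties
    order = np.argsort(-probs, kind="stable")[:k]
    mask = np.zeros((n, n))
    for idx in order:
        i, j = pairs[idx]
        mask[i, j] = mask[j, i] = 1.0
    return EdgeMask(mask=mask, retained_count=k)


def apply_mask(matrix: ConnectivityMatrix, mask: EdgeMask) -> ConnectivityMatrix:
    """Zero a subject's matrix outside the group mask (entrywise product)."""
    if matrix.values.shape != mask.mask.shape:
        raise ValueError("matrix and mask shapes differ")
    return ConnectivityMatrix(
        values=matrix.values * mask.mask, node_labels=list(matrix.node_labels)
    )
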