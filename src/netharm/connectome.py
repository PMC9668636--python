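"""Per-subject connectivity matrices and group-level probability / FA matrices.

Nodes are gray-matter parcels (90 regions by default, mirroring the AAL
atlas); an edge exists when tractography places at least one streamline
between two parcels.  Group-level summaries are the connection-probability
matrix (entrywise mean of binary matrices — an entry of 0.5 means the edge is
detected in 50% of subjects) and the group FA matrix (mean FA over the
subjects in which the edge is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "GroupMatrices",
    "binarize",
    "group_probability",
    "group_fa",
    "upper_triangle_pairs",
]


def _default_labels(n: int) -> list[str]:
    return [f"node{i:03d}" for i in range(n)]


@dataclass
class ConnectivityMatrix:
    """Symmetric node-by-node matrix: streamline counts, binary, or FA weights."""

    values: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(values, values.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("connectivity matrix must have zero diagonal")
        if np.any(values < 0):
            raise ValueError("connectivity matrix must be non-negative")
        self.values = values
        if not self.node_labels:
            self.node_labels = _default_labels(values.shape[0])
        elif len(self.node_labels) != values.shape[0]:
            raise ValueError("node_labels length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        """Write as TSV with node labels in header row and first column."""
        pd.DataFrame(self.values, index=self.node_labels, columns=self.node_labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=frame.to_numpy(dtype=float), node_labels=list(frame.columns))


@dataclass
class GroupMatrices:
    """Group connection-probability and group-mean-FA matrices for one cohort."""

    probability: np.ndarray  # entries in [0, 1]
    group_fa: np.ndarray  # nonzero only where probability > 0
    n_subjects: int
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.probability < 0) or np.any(self.probability > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any((self.group_fa > 0) & (self.probability == 0)):
            raise ValueError("group FA must be zero where probability is zero")
        if not self.node_labels:
            self.node_labels = _default_labels(self.probability.shape[0])


def _check_same_labels(matrices: list[ConnectivityMatrix]) -> None:
    labels = matrices[0].node_labels
    for m in matrices[1:]:
        if m.node_labels != labels:
            raise ValueError("node labels differ across subjects")


def binarize(counts: ConnectivityMatrix) -> ConnectivityMatrix:
    """Binary matrix: 1 iff at least one streamline connects the node pair."""
    return ConnectivityMatrix(
        values=(counts.values >= 1).astype(float), node_labels=list(counts.node_labels)
    )


def group_probability(binaries: list[ConnectivityMatrix]) -> np.ndarray:
    """Entrywise mean of subjects' binary matrices (connection probability)."""
    if not binaries:
        raise ValueError("need at least one subject")
    _check_same_labels(binaries)
    return np.mean([b.values for b in binaries], axis=0)


def group_fa(
    fa_matrices: list[ConnectivityMatrix], binaries: list[ConnectivityMatrix]
) -> np.ndarray:
    """Per-edge mean FA over the subjects in which the edge is present.

    Absent edges are treated as missing, not as FA 0 — averaging in zeros
    would conflate tract absence with low anisotropy.  Entries where no
    subject has the edge are 0.
    """
    if len(fa_matrices) != len(binaries) or not fa_matrices:
        raise ValueError("need matched, non-empty FA and binary matrix lists")
    _check_same_labels(fa_matrices)
    _check_same_labels(binaries)
    fa_stack = np.array([m.values for m in fa_matrices])
    present = np.array([b.values > 0 for b in binaries])
    if np.any(fa_stack < 0) or np.any(fa_stack > 1):
        raise ValueError("FA values must lie in [0, 1]")
    if np.any((fa_stack > 0) & ~present):
        raise ValueError("FA must be zero where the binary matrix is zero")
    counts = present.sum(axis=0)
    totals = np.where(present, fa_stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_fa = np.where(counts > 0, totals / np.maximum(counts, 1), 0.0)
    return mean_fa


def build_group_matrices(
    fa_matrices: list[ConnectivityMatrix], binaries: list[ConnectivityMatrix]
) -> GroupMatrices:
    """Convenience constructor pairing group probability with group FA."""
    return GroupMatrices(
        probability=group_probability(binaries),
        group_fa=group_fa(fa_matrices, binaries),
        n_subjects=len(binaries),
        node_labels=list(binaries[0].node_labels),
    )


def upper_triangle_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """All unordered node pairs (i < j) in lexicographic order."""
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
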