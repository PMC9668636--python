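"""Cross-site consistency of network architecture.

Two sites' group matrices (connection probability, or group FA) are compared
edge by edge with the symmetric relative difference

    difference = 100% * |Site1 - Site2| / ((Site1 + Site2) / 2)

which is bounded in [0, 200] and equals 200 when an edge is present at one
site only.  Lower values mean higher cross-site consistency.  Summaries are
taken over the union support — every edge where at least one site has a
nonzero entry; edges absent from both sites are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConsistencyResult", "relative_difference"]


@dataclass
class ConsistencyResult:
    """Edgewise and summary relative difference (percent) between two sites."""

    edgewise: np.ndarray  # percent, NaN off support
    summary_mean: float  # percent, mean over union support
    summary_max: float  # percent
    support_count: int  # edges with nonzero entry at either site

    def __str__(self) -> str:  # percentages to 1 decimal, reporting convention
        return (
            f"mean relative difference {self.summary_mean:.1f}% "
            f"(max {self.summary_max:.1f}%, {self.support_count} edges)"
        )


def relative_difference(a: np.ndarray, b: np.ndarray) -> ConsistencyResult:
    """Symmetric percent relative difference between two group matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("group matrix entries must be non-negative")
    support = (a + b) > 0
    edgewise = np.full(a.shape, np.nan)
    mean_ab = (a[support] + b[support]) / 2.0
    edgewise[support] = 100.0 * np.abs(a[support] - b[support]) / mean_ab
    iu = np.triu_indices(a.shape[0], k=1)
    upper = edgewise[iu]
    on_support = upper[~np.isnan(upper)]
    if on_support.size == 0:
        return ConsistencyResult(edgewise=edgewise, summary_mean=0.0, summary_max=0.0, support_count=0)
    return ConsistencyResult(
        edgewise=edgewise,
        summary_mean=float(np.mean(on_support)),
        summary_max=float(np.max(on_support)),
        support_count=int(on_support.size),
    )
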