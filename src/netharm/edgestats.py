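"""Edgewise group comparison with permutation-based FDR (NBS-style).

For every network connection, the FA of subjects possessing that edge is
adjusted for age and sex by ordinary-least-squares residualization, then
compared between controls and patients with a pooled-variance two-sample
t-test and Cohen's d.  Significance is assessed empirically: group labels are
permuted (residuals held fixed — the Freedman–Lane simplification), per-edge
two-sided p-values are computed as

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)

and Benjamini–Hochberg step-up across all tested edges yields q-values.

Subjects lacking an edge are excluded from that edge's test rather than
entered with FA 0: a missing tract is missing data, not zero anisotropy.  An
edge is testable when at least two usable subjects remain in each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectome import ConnectivityMatrix, upper_triangle_pairs
from .thresholding import EdgeMask

__all__ = [
    "EdgeData",
    "EdgewiseResults",
    "StageDetections",
    "residualize",
    "edge_ttest",
    "cohens_d",
    "permutation_fdr",
    "stage_detections",
    "edge_data_from_matrices",
]

MIN_PERMUTATIONS = 100


@dataclass
class EdgeData:
    """Per-subject edge values with covariates; NaN marks an absent edge."""

    values: np.ndarray  # (n_subjects, n_edges), NaN where edge absent
    is_control: np.ndarray  # (n_subjects,) bool
    age: np.ndarray  # years
    sex: np.ndarray  # {0, 1}
    edges: list[tuple[int, int]]  # node pairs, aligned with columns

    def __post_init__(self) -> None:
        n = self.values.shape[0]
        for name in ("is_control", "age", "sex"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per subject")
        if len(self.edges) != self.values.shape[1]:
            raise ValueError("edge list must align with value columns")
        if not (np.any(self.is_control) and np.any(~self.is_control)):
            raise ValueError("both groups must be non-empty")


@dataclass
class StageDetections:
    """Nested detection sets at the three reporting stages."""

    large_effect: set[tuple[int, int]]
    surviving_threshold: set[tuple[int, int]]
    surviving_fdr: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.surviving_threshold <= self.large_effect:
            raise ValueError("surviving_threshold must be a subset of large_effect")
        if not self.surviving_fdr <= self.surviving_threshold:
            raise ValueError("surviving_fdr must be a subset of surviving_threshold")


@dataclass
class EdgewiseResults:
    """Per-edge statistics table plus the settings that produced it."""

    table: pd.DataFrame  # node_i node_j n_control n_patient t d p_perm q_fdr testable
    n_perm: int
    seed: int
    q_level: float = 0.05

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def residualize(values: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """OLS residuals of values on intercept + age + sex (groups pooled).

    Requires >= 3 observations and a full-rank design; residuals have mean 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("residualization needs at least 3 subjects")
    design = np.column_stack([np.ones_like(values), np.asarray(age, float), np.asarray(sex, float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design (constant age and sex?)")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def _group_stats(values: np.ndarray, is_control: np.ndarray):
    vc, vp = values[is_control], values[~is_control]
    if len(vc) < 2 or len(vp) < 2:
        raise ValueError("need at least 2 usable subjects per group")
    n1, n0 = len(vc), len(vp)
    sp2 = ((n1 - 1) * np.var(vc, ddof=1) + (n0 - 1) * np.var(vp, ddof=1)) / (n1 + n0 - 2)
    return vc.mean() - vp.mean(), np.sqrt(sp2), n1, n0


def edge_ttest(values: np.ndarray, is_control: np.ndarray) -> float:
    """Pooled-variance two-sample t; positive when controls exceed patients."""
    diff, sp, n1, n0 = _group_stats(np.asarray(values, float), np.asarray(is_control, bool))
    if sp == 0:
        raise ValueError("zero pooled variance: edge untestable")
    return diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n0))


def cohens_d(values: np.ndarray, is_control: np.ndarray) -> float:
    """Standardized mean difference (controls - patients) / pooled SD."""
    diff, sp, _, _ = _group_stats(np.asarray(values, float), np.asarray(is_control, bool))
    if sp == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return diff / sp


def _batch_t(resid: np.ndarray, mask: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled t per edge column for one label assignment; NaN where untestable.

    ``resid`` has 0 at missing entries, ``mask`` is the usable indicator,
    ``labels`` is 1 for controls.
    """
    z = labels.astype(float)
    n1 = z @ mask
    n0 = (1.0 - z) @ mask
    s1 = z @ resid
    s0 = (1.0 - z) @ resid
    ss = ((resid**2) * mask).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        within = ss - s1**2 / n1 - s0**2 / n0
        df = n1 + n0 - 2
        sp2 = within / df
        t = (s1 / n1 - s0 / n0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    bad = (n1 < 2) | (n0 < 2) | (sp2 <= 0) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    return t


def permutation_fdr(
    data: EdgeData,
    n_perm: int = 50_000,
    seed: int = 0,
    q_level: float = 0.05,
) -> EdgewiseResults:
    """Edgewise permutation test with Benjamini–Hochberg FDR across edges.

    Residualization (age + sex) is performed once per edge over its usable
    subjects; permutations shuffle group labels over all subjects, and each
    edge's permuted statistic uses whatever usable subjects fall in each
    group.  Deterministic given ``seed``.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be at least {MIN_PERMUTATIONS}")
    rng = np.random.default_rng(seed)
    values = np.asarray(data.values, dtype=float)
    usable = ~np.isnan(values)
    n_subjects, n_edges = values.shape
    is_control = np.asarray(data.is_control, bool)

    resid = np.zeros_like(values)
    n_control = (usable & is_control[:, None]).sum(axis=0)
    n_patient = (usable & ~is_control[:, None]).sum(axis=0)
    testable = (n_control >= 2) & (n_patient >= 2)
    for e in range(n_edges):
        if not testable[e]:
            continue
        idx = usable[:, e]
        try:
            resid[idx, e] = residualize(values[idx, e], data.age[idx], data.sex[idx])
        except ValueError:
            testable[e] = False

    mask = (usable & testable[None, :]).astype(float)
    resid = resid * mask

    t_obs = _batch_t(resid, mask, is_control)
    testable &= np.isfinite(t_obs)
    t_obs = np.where(testable, t_obs, np.nan)

    d_obs = t_obs * np.sqrt(
        np.where(testable, 1.0 / np.maximum(n_control, 1) + 1.0 / np.maximum(n_patient, 1), np.nan)
    )

    exceed = np.zeros(n_edges)
    valid_perms = np.zeros(n_edges)
    abs_obs = np.abs(t_obs)
    for _ in range(n_perm):
        perm_labels = rng.permutation(is_control)
        t_perm = _batch_t(resid, mask, perm_labels)
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(t_perm), 0.0, (np.abs(t_perm) >= abs_obs).astype(float))
        valid_perms += np.isfinite(t_perm)

    p_perm = np.full(n_edges, np.nan)
    denom = np.where(valid_perms > 0, valid_perms, n_perm)
    p_perm[testable] = (1.0 + exceed[testable]) / (denom[testable] + 1.0)

    q_fdr = np.full(n_edges, np.nan)
    if np.any(testable):
        _, q, *_ = multipletests(p_perm[testable], alpha=q_level, method="fdr_bh")
        q_fdr[testable] = q

    table = pd.DataFrame(
        {
            "node_i": [e[0] for e in data.edges],
            "node_j": [e[1] for e in data.edges],
            "n_control": n_control,
            "n_patient": n_patient,
            "t": t_obs,
            "d": d_obs,
            "p_perm": p_perm,
            "q_fdr": q_fdr,
            "testable": testable,
        }
    )
    return EdgewiseResults(table=table, n_perm=n_perm, seed=seed, q_level=q_level)


def stage_detections(
    results: EdgewiseResults,
    mask: EdgeMask,
    d_threshold: float = 0.8,
    q_level: float = 0.05,
    signed: bool = True,
) -> StageDetections:
    """Nested detection sets: large effect, inside mask, and FDR-surviving.

    ``signed=True`` gates on d > d_threshold (FA reduced in patients);
    ``signed=False`` gates on |d| > d_threshold.
    """
    tab = results.table
    d = tab["d"].to_numpy()
    effect = d > d_threshold if signed else np.abs(d) > d_threshold
    effect &= tab["testable"].to_numpy()
    mask_edges = mask.edge_set()
    large = {
        (int(i), int(j))
        for i, j, keep in zip(tab["node_i"], tab["node_j"], effect)
        if keep
    }
    surviving_threshold = large & mask_edges
    sig = tab["q_fdr"].to_numpy() < q_level
    fdr_edges = {
        (int(i), int(j))
        for i, j, keep, s in zip(tab["node_i"], tab["node_j"], effect, sig)
        if keep and s
    }
    surviving_fdr = fdr_edges & surviving_threshold
    return StageDetections(
        large_effect=large,
        surviving_threshold=surviving_threshold,
        surviving_fdr=surviving_fdr,
    )


def edge_data_from_matrices(
    fa_matrices: list[ConnectivityMatrix],
    binaries: list[ConnectivityMatrix],
    is_control: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> EdgeData:
    """Stack subjects' FA matrices into an (n_subjects, n_pairs) edge table."""
    if len(fa_matrices) != len(binaries) or not fa_matrices:
        raise ValueError("need matched, non-empty FA and binary lists")
    n = fa_matrices[0].n_nodes
    pairs = upper_triangle_pairs(n)
    iu = np.triu_indices(n, k=1)
    values = np.empty((len(fa_matrices), len(pairs)))
    for s, (fa, bin_) in enumerate(zip(fa_matrices, binaries)):
        present = bin_.values[iu] > 0
        row = fa.values[iu]
        values[s] = np.where(present, row, np.nan)
    return EdgeData(
        values=values,
        is_control=np.asarray(is_control, bool),
        age=np.asarray(age, float),
        sex=np.asarray(sex, float),
        edges=pairs,
    )
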