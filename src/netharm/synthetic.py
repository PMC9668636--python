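"""Synthetic multi-site structural-connectome cohorts with known ground truth.

The generator emulates the ingredients of a multi-centre diffusion-MRI network
study:

* a shared "core" network of anatomically consistent edges, each detected in a
  subject with a specified probability;
* subject-random spurious edges (tractography false positives) scattered
  uniformly over non-core node pairs, giving the familiar haze of
  low-probability connections at group level;
* per-site scanner effects, expressed as multiplicative scalings of the
  per-order spherical-harmonic signal power — exactly the distortion family
  that RISH harmonization models — which induce site offsets in
  fractional anisotropy;
* a planted set of disease-affected edges whose FA is reduced in patients.

Edge FA is not drawn directly: each present edge gets a single-tensor signal
with the target anisotropy, the site's per-order scaling and measurement noise
are applied to that signal, and FA is re-estimated by the tensor fit.  This
keeps the harmonization -> network coupling honest: rescaling the signal back
genuinely restores the FA weights downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rish
from .connectome import ConnectivityMatrix, upper_triangle_pairs

__all__ = [
    "SiteSpec",
    "NetworkTruth",
    "SubjectRecord",
    "generate_cohort",
    "generate_dwi_phantom",
    "default_truth",
    "default_sites",
    "write_cohort",
]

_ANATOMY_SEED = 20_220_103  # fixes the shared anatomy (core edges, orientations)
_PHANTOM_TRUTH_SEED = 20_221_003  # fixes the phantom's shared SH ground truth
_SIGNAL_FLOOR = 1e-3


@dataclass(frozen=True)
class SiteSpec:
    """Acquisition-site description, including its scanner effect.

    ``sh_order_scales`` maps each even SH order l to the multiplicative factor
    applied to the site's order-l signal *power* (so coefficients are scaled
    by its square root); all-ones means the site is indistinguishable from the
    reference.  ``noise_sd`` is the Gaussian signal noise as a fraction of the
    b=0 signal.
    """

    site_id: str
    n_controls: int
    n_patients: int
    sh_order_scales: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.02
    age_mean: float = 70.0
    age_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("subject counts must be non-negative")
        if any(v <= 0 for v in self.sh_order_scales.values()):
            raise ValueError("sh_order_scales must be strictly positive")
        if any(l % 2 != 0 for l in self.sh_order_scales):
            raise ValueError("sh_order_scales keys must be even SH orders")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class NetworkTruth:
    """Planted network ground truth shared by all sites.

    ``core_edges`` maps unordered node pairs to per-subject detection
    probabilities; ``affected_edges`` is the planted disease signature (a
    subset of the core), whose mean FA is reduced by ``disease_delta`` in
    patients.  ``spurious_edge_rate`` is the expected number of random
    non-core edges added per subject.
    """

    n_nodes: int = 90
    core_edges: dict[tuple[int, int], float] = field(default_factory=dict)
    spurious_edge_rate: float = 120.0
    affected_edges: frozenset = frozenset()
    fa_baseline: dict[tuple[int, int], float] = field(default_factory=dict)
    spurious_fa: float = 0.40
    fa_subject_sd: float = 0.04
    disease_delta: float = 0.05

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        for edge, p in self.core_edges.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detection probability {p} outside [0, 1] for {edge}")
            if not (0 <= edge[0] < edge[1] < self.n_nodes):
                raise ValueError(f"invalid node pair {edge}")
        if not set(self.affected_edges) <= set(self.core_edges):
            raise ValueError("affected_edges must be a subset of core_edges")
        for fa in self.fa_baseline.values():
            if not 0.0 < fa < 1.0:
                raise ValueError("fa_baseline values must lie in (0, 1)")
        if self.disease_delta < 0:
            raise ValueError("disease_delta must be non-negative")
        if self.spurious_edge_rate < 0:
            raise ValueError("spurious_edge_rate must be non-negative")

    def baseline_for(self, edge: tuple[int, int]) -> float:
        return self.fa_baseline.get(edge, self.spurious_fa)


@dataclass
class SubjectRecord:
    """One synthetic subject: covariates, matrices, and raw per-edge signals."""

    subject_id: str
    site_id: str
    group: str  # "control" | "patient"
    age: float
    sex: int  # {0, 1}
    count_matrix: ConnectivityMatrix
    fa_matrix: ConnectivityMatrix
    edge_index: list[tuple[int, int]] = field(default_factory=list)
    edge_signals: np.ndarray | None = None  # (n_present_edges, n_measurements)

    @property
    def is_control(self) -> bool:
        return self.group == "control"


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _edge_signals(
    target_fa: np.ndarray, orientations: np.ndarray, scheme: rish.GradientScheme
) -> np.ndarray:
    """Noise-free single-tensor signals for a batch of edges.

    Each edge gets an axially symmetric tensor with the target FA (mean
    diffusivity fixed at 0.7e-3 mm^2/s) rotated to its orientation.
    """
    n_edges = len(target_fa)
    tensors = np.empty((n_edges, 3, 3))
    for k in range(n_edges):
        evals = rish.eigenvalues_from_fa(float(target_fa[k]))
        rot = orientations[k]
        tensors[k] = rot @ np.diag(evals) @ rot.T
    g = scheme.directions
    b = scheme.bvalues
    adc = np.einsum("ni,kij,nj->kn", g, tensors, g)
    return np.exp(-b[None, :] * adc)


def _apply_site_scaling(
    signals: np.ndarray, scales: dict[int, float], scheme: rish.GradientScheme, lmax: int = 6
) -> np.ndarray:
    """Scale each SH order's coefficients by sqrt(scale_l) and resynthesize.

    All signals pass through the same lmax band limit, so sites with unit
    scales share the truncation with distorted sites.
    """
    coeffs = rish.fit_sh(signals, scheme, lmax=lmax)
    order_scale = np.array([np.sqrt(scales.get(l, 1.0)) for l, _ in coeffs.lm])
    scaled = rish.SHCoefficients(
        coefficients=coeffs.coefficients * order_scale[None, :], lmax=lmax, b0=coeffs.b0
    )
    return rish.resynthesize(scaled, scheme)


def generate_cohort(
    site: SiteSpec,
    truth: NetworkTruth,
    scheme: rish.GradientScheme | None = None,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Generate one site's controls and patients with planted ground truth.

    Deterministic given ``seed`` (defaults to ``site.seed``).  Edge FA is
    produced through the signal model: single-tensor signal at the subject's
    target FA -> site per-order scaling -> Gaussian noise -> tensor fit.
    """
    scheme = scheme or rish.make_scheme()
    seed = site.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    anatomy_rng = np.random.default_rng(_ANATOMY_SEED)

    core = sorted(truth.core_edges)
    core_probs = np.array([truth.core_edges[e] for e in core])
    all_pairs = upper_triangle_pairs(truth.n_nodes)
    non_core = [p for p in all_pairs if p not in truth.core_edges]
    # per-edge fibre orientation is anatomy: shared across subjects and sites
    orientation_of = {e: _random_rotation(anatomy_rng) for e in core}

    subjects: list[SubjectRecord] = []
    groups = ["control"] * site.n_controls + ["patient"] * site.n_patients
    for k, group in enumerate(groups):
        present_core = [e for e, p in zip(core, rng.random(len(core)) < core_probs) if p]
        n_spurious = min(rng.poisson(truth.spurious_edge_rate), len(non_core))
        spurious_idx = rng.choice(len(non_core), size=n_spurious, replace=False)
        spurious = [non_core[i] for i in spurious_idx]
        edges = present_core + spurious

        target_fa = np.empty(len(edges))
        for i, e in enumerate(edges):
            fa = truth.baseline_for(e) + rng.normal(0.0, truth.fa_subject_sd)
            if group == "patient" and e in truth.affected_edges:
                fa -= truth.disease_delta
            target_fa[i] = np.clip(fa, 0.05, 0.95)

        orientations = np.array(
            [orientation_of.get(e, _random_rotation(rng)) for e in edges]
        )
        signals = _edge_signals(target_fa, orientations, scheme)
        signals = _apply_site_scaling(signals, site.sh_order_scales, scheme)
        if site.noise_sd > 0:
            signals = signals + rng.normal(0.0, site.noise_sd, size=signals.shape)
        signals = np.maximum(signals, _SIGNAL_FLOOR)

        fa_values = rish.fit_tensor_fa(signals, scheme)
        fa_values = np.atleast_1d(fa_values)

        counts = np.zeros((truth.n_nodes, truth.n_nodes))
        fa_mat = np.zeros((truth.n_nodes, truth.n_nodes))
        streamlines = 1 + rng.poisson(20.0, size=len(edges))
        for (i, j), c, fa in zip(edges, streamlines, fa_values):
            counts[i, j] = counts[j, i] = c
            fa_mat[i, j] = fa_mat[j, i] = fa

        age = float(np.clip(rng.normal(site.age_mean, site.age_sd), 50.0, 90.0))
        subjects.append(
            SubjectRecord(
                subject_id=f"{site.site_id}_{group[0]}{k:03d}",
                site_id=site.site_id,
                group=group,
                age=age,
                sex=k % 2,
                count_matrix=ConnectivityMatrix(values=counts),
                fa_matrix=ConnectivityMatrix(values=fa_mat),
                edge_index=edges,
                edge_signals=signals,
            )
        )
    return subjects


def generate_dwi_phantom(
    site: SiteSpec,
    n_voxels: int,
    scheme: rish.GradientScheme | None = None,
    seed: int | None = None,
    lmax: int = 6,
) -> list[np.ndarray]:
    """Voxel-level DWI phantoms for the site's controls.

    Every voxel carries ground-truth SH coefficients shared across sites
    (derived from random single-tensor profiles under a fixed internal seed);
    the site multiplies the order-l coefficients by sqrt(sh_order_scales[l]),
    resynthesizes on the scheme, and adds per-subject Gaussian noise.
    Returns one (n_voxels, n_measurements) array per control subject.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be at least 1")
    scheme = scheme or rish.make_scheme()
    seed = site.seed if seed is None else seed
    truth_rng = np.random.default_rng(_PHANTOM_TRUTH_SEED)
    target_fa = truth_rng.uniform(0.1, 0.85, size=n_voxels)
    orientations = np.array([_random_rotation(truth_rng) for _ in range(n_voxels)])
    clean = _edge_signals(target_fa, orientations, scheme)
    # shared ground truth is the band-limited SH representation of these profiles
    scaled = _apply_site_scaling(clean, site.sh_order_scales, scheme, lmax=lmax)

    rng = np.random.default_rng(seed)
    # no positivity clamp here: phantoms feed linear SH fits, and clamping
    # would break the exact per-order linearity of the site scaling
    return [
        scaled + rng.normal(0.0, site.noise_sd, size=scaled.shape)
        for _ in range(site.n_controls)
    ]


def default_truth(
    n_nodes: int = 90,
    n_core: int = 550,
    n_affected: int = 150,
    spurious_edge_rate: float = 120.0,
    disease_delta: float = 0.05,
    fa_subject_sd: float = 0.04,
    seed: int = _ANATOMY_SEED,
) -> NetworkTruth:
    """Default planted truth: 90 nodes, 550 high-probability core edges
    (detection probability 0.75-1.0, baseline FA 0.35-0.55), a planted
    signature of 150 affected edges — the scale of a severe-disease reference
    pattern — and ~120 spurious edges per subject."""
    rng = np.random.default_rng(seed)
    pairs = upper_triangle_pairs(n_nodes)
    core_idx = rng.choice(len(pairs), size=n_core, replace=False)
    core = {pairs[i]: float(p) for i, p in zip(core_idx, rng.uniform(0.75, 1.0, n_core))}
    fa_baseline = {e: float(v) for e, v in zip(core, rng.uniform(0.35, 0.55, n_core))}
    affected = frozenset(
        sorted(core)[i] for i in rng.choice(n_core, size=n_affected, replace=False)
    )
    return NetworkTruth(
        n_nodes=n_nodes,
        core_edges=core,
        spurious_edge_rate=spurious_edge_rate,
        affected_edges=affected,
        fa_baseline=fa_baseline,
        fa_subject_sd=fa_subject_sd,
        disease_delta=disease_delta,
    )


def default_sites(seed: int = 0) -> list[SiteSpec]:
    """Default three-site layout: a reference site plus two sporadic-disease
    sites with distinct per-order scanner scalings and site-confounded group
    proportions (pooled: 80 controls / 80 patients)."""
    return [
        SiteSpec(site_id="siteA", n_controls=15, n_patients=0, sh_order_scales={}, seed=seed + 11),
        SiteSpec(
            site_id="siteB",
            n_controls=50,
            n_patients=30,
            sh_order_scales={0: 0.90, 2: 1.25},
            seed=seed + 22,
        ),
        SiteSpec(
            site_id="siteC",
            n_controls=30,
            n_patients=50,
            sh_order_scales={0: 1.15, 2: 0.85},
            seed=seed + 33,
        ),
    ]


def write_cohort(subjects: list[SubjectRecord], out_dir) -> pd.DataFrame:
    """Write per-subject count/FA TSV matrices and a covariates CSV.

    Returns the covariate table (subject_id, site_id, group, age, sex).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        s.count_matrix.to_tsv(out / f"{s.subject_id}_counts.tsv")
        s.fa_matrix.to_tsv(out / f"{s.subject_id}_fa.tsv")
        rows.append(
            {
                "subject_id": s.subject_id,
                "site_id": s.site_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "covariates.csv", index=False)
    return table
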