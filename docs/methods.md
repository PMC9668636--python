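# Methods

## Signal model and harmonization core

The diffusion-weighted signal of a voxel (or, in the synthetic cohorts, of a
white-matter connection) is represented in a real, even-order spherical
harmonic (SH) basis with maximum order 6 — 28 coefficients, requiring at
least 28 distinct nonzero-b directions.  The basis is orthonormal:
`sqrt(2)·Im(Y_l^|m|)` for m < 0, `Y_l^0` for m = 0, `sqrt(2)·Re(Y_l^m)` for
m > 0, columns ordered lexicographically in (l, m).  Antipodal symmetry of
the dMRI signal makes odd orders identically zero, so they are omitted.  The
b = 0 volumes are excluded from the angular fit; their per-voxel mean
normalizes the diffusion-weighted signal before fitting and is retained for
resynthesis.  Fitting is plain linear least squares; on the default
45-direction Fibonacci-sphere scheme the design matrix has condition number
≈ 1.5, so no regularization is needed.

The rotation-invariant per-order power `E_l = Σ_m c_lm²` summarizes the
signal's angular energy.  Scanner and protocol differences are modelled as
per-order multiplicative power distortions; harmonization estimates, from
the RISH features of matched controls of a site and of a reference site,

    s_l = sqrt( mean_ref(E_l) / mean_site(E_l) ),     s_l := 1 where mean_site(E_l) = 0,

and multiplies every order-l coefficient by `s_l` before resynthesis.  The
zero-power guard avoids division by zero; such voxels carry no order-l
energy to rescale.  Because the maps are group-level and monotone, they
preserve between-subject rank order and variance structure.

Scale maps are defined per voxel on a shared synthetic grid.  The package
has no registration/template machinery (out of scope): the shared phantom
grid plays the template's role.  When maps are applied to cohort edge
signals — whose "voxels" differ per subject — the voxel-mean per-order
scales are used, which is exact here because the simulated scanner effect is
spatially uniform by construction.

FA is computed by a log-linear least-squares tensor fit (≥ 6 nonzero-b
directions plus b = 0, strictly positive signals), with
`FA = sqrt(3/2)·||λ − λ̄|| / ||λ||` clamped to [0, 1].  Robust estimators and
Rician-bias handling are intentionally absent; single-shell schemes only.

## Synthetic multi-site cohorts

The generator emulates the structure of a multi-centre SVD network study
without claiming demographic realism:

* **Core network**: 550 of the 4005 possible 90-node pairs, each detected
  per subject with probability drawn once from U(0.75, 1.0); baseline FA per
  edge from U(0.35, 0.55).  Spurious edges are resampled independently per
  subject, uniformly over non-core pairs, at a Poisson rate of 120 per
  subject — producing the group-level haze of low-probability connections
  that thresholding is meant to remove.  Edge "anatomy" (which pairs are
  core, their fibre orientations) is fixed by an internal seed so all sites
  observe the same network.
* **Edge FA through the signal model**: each present edge gets an axially
  symmetric tensor with the subject's target FA (mean diffusivity fixed at
  0.7·10⁻³ mm²/s; the axial/radial split is the closed-form inverse of the
  FA formula), sampled on the gradient scheme, passed through the site's
  per-order SH scaling, noised (Gaussian on the signal, sd = 0.02 of b0 by
  default; Rician bias is out of scope), floored at 10⁻³ for the log-space
  fit, and re-fitted.  FA is therefore *not* drawn directly, so harmonizing
  the signal genuinely restores the downstream edge weights.
* **Disease signature**: 150 core edges (the scale of a severe-disease
  reference pattern) lose `disease_delta = 0.05` FA in patients.  With
  between-subject FA sd 0.04 plus fit noise, the planted standardized effect
  is near 1 — the regime the recovery analysis targets.  The signature size
  also matters statistically: with ~4000 edges tested and an empirical
  p-value floor of 1/(n_perm+1), Benjamini–Hochberg can only reject when
  enough edges share the floor; a signature of 150 comfortably clears that
  bar at 1000 permutations.
* **Sites**: a clean reference site plus two disease sites with opposing
  per-order scalings ({0: 0.90, 2: 1.25} and {0: 1.15, 2: 0.85}) and
  site-confounded group proportions (50/30 and 30/50 controls/patients,
  pooling to 80 vs 80).  The confounding direction is chosen so that the
  patient-heavy site carries the FA-lowering scanner effect, reproducing the
  effect-size inflation seen when pooling non-harmonized data.  Covariates
  exist for adjustment only: ages N(70, 8) truncated to [50, 90], sex
  alternating.
* **DWI phantoms**: shared ground-truth SH coefficients per voxel (from
  random single-tensor profiles under a fixed internal seed), site-scaled
  and noised per subject.  Phantoms feed linear SH fits, so no positivity
  clamp is applied there — clamping would break the exact per-order
  linearity that the scale-map tests rely on.

What the generator does **not** emulate: realistic tractography geometry,
lesions, motion/eddy artifacts, multi-shell acquisitions, spatially varying
scanner effects, demographic site differences.  Passing tests therefore show
that the pipeline's logic is correct under its own model assumptions, not
that harmonization removes arbitrary real-world scanner effects.

## Statistical procedure

Per edge, FA values of the subjects possessing the edge (absence is missing
data, not FA 0) are residualized on intercept + age + sex over both groups
pooled, then compared with a pooled-variance two-sample t-test, sign =
controls − patients.  Cohen's d uses the same pooled SD; the large-effect
gate is signed d > 0.8 (an absolute-value variant is a flag).  Significance
is empirical: group labels are permuted with residuals held fixed (the
Freedman–Lane simplification), and

    p = (1 + #{|t_perm| ≥ |t_obs|}) / (n_perm + 1)

is corrected across all tested edges by Benjamini–Hochberg at q = 0.05
(statsmodels implementation).  Edges need ≥ 2 usable subjects per group; in
permutations where an edge's group falls below 2 or its variance vanishes,
that permutation is skipped for that edge and the denominator adjusted.
Default n_perm is 50,000; the experiment driver and tests use 1000, which
keeps each property run in seconds-to-minutes while leaving the p-value
floor (≈ 10⁻³) small enough for the analyses performed.

Detection stages nest by construction: {d > 0.8} ⊇ {∩ density mask} ⊇
{∩ q < 0.05}.  Thresholding retains the K = floor(density · n(n−1)/2)
highest-probability edges (floor keeps realized density at or below target
and identical across sites); ties at the cutoff break lexicographically by
node pair, making masks reproducible.

Cross-site consistency summaries average the edgewise relative difference
over the **union** support (either site nonzero); edges absent from both
sites are excluded.  The union choice is deliberate: one-sided edges are
exactly the inconsistency the statistic should see (they contribute the
maximum, 200%).  The maximum is reported alongside the mean.

## Experiment design

`run_experiment` generates all cohorts, estimates scale maps from
15 training controls per site on a 150-voxel phantom grid, harmonizes every
disease site to the reference, and reports: (a) consistency of the training
controls' group matrices under four conditions — none, harmonization only,
thresholding only, both; (b) staged detections per site and for the pooled
cohort before/after harmonization, each cohort thresholded on its own group
probability matrix; (c) precision of every stage against a reference edge
set built from a separately simulated high-burden cohort (28 controls, 54
patients, planted FA loss scaled ×1.6 — the analog of using a severe
monogenic form of the disease as reference standard); (d) recovery of the
planted truth by the pooled analyses.  Everything is deterministic given the
config seed; per-cohort analysis seeds are derived from it.

## Numerical choices and degenerate inputs

* SH fit raises with the required direction count when underdetermined.
* Tensor fit rejects non-positive signals (log space); generated signals are
  floored at 10⁻³ of b0 before fitting.
* `s_l := 1` where the site's mean power is zero; non-finite ratios map to 1.
* Thresholding with fewer nonzero edges than K retains all nonzero entries
  and logs a warning (realized density below target).
* Empty detected sets score precision "N/A"; an empty reference makes
  precision undefined and is rejected with a warning at construction.
* Percentages are reported to one decimal, precisions to two — matching the
  conventions of multi-centre network reports.

## Known limitations

Voxelwise scale maps are exercised only with spatially uniform site effects;
the per-order mean application would be approximate for spatially varying
effects.  The permutation scheme assumes exchangeability of residualized
subjects across sites within the pooled analyses (no site covariate in the
non-harmonized pooling — deliberately, to expose the confounding that
harmonization is meant to fix).  The empirical-p + BH composition is
conservative relative to max-statistic familywise procedures but is not the
only defensible estimator.
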