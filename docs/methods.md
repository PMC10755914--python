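# Methods

## Boundary model

The package treats the gray-white interface as an intensity band. Two
per-subject pools anchor it: voxels with GM partial-volume fraction
strictly above 0.5 and voxels with WM fraction strictly above 0.5 ("more
than 50% volume" is read as a strict inequality; ties at exactly 0.5 are
excluded, a measure-zero choice on continuous data). With pool mean m and
sample SD s (n−1 denominator; at pool sizes in the thousands the n vs n−1
distinction is negligible, but the sample convention is fixed), the band is
`[m_GM + s_GM, m_WM − s_WM]` — i.e. mean plus/minus half of a 2·SD
dispersion term. Intensities inside the band, at voxels whose combined
GM+WM fraction exceeds 0.5, form the binary boundary map gwBB. The
eligibility rule exists because CSF and background voxels can carry
band-range intensities purely by partial-volume mixing or noise; requiring
majority GM/WM tissue keeps them out. A degenerate band (lower ≥ upper,
possible when pools overlap heavily) produces an empty gwBB with a warning
rather than an error, since it is a legitimate outcome for a severely
degraded image.

The boundary density (gwBTV) is gwBB convolved with a normalized box
kernel, default 5×5×5, zero-padded at the grid edge. Normalization keeps
values in [0, 1] and makes the control-cohort mean map interpretable as a
boundary probability. With the normalized kernel the conserved quantity is
`sum(density) = sum(gwBB)`, exact whenever no boundary mass lies within the
kernel radius of the grid edge; windows that fall off the grid lose their
share. Kernel size 1 is the identity; even sizes are rejected (no centred
window).

## Normative Z-scoring

The normative model is the voxelwise mean and sample SD of control
densities. gwBZ = (individual − mean)/SD, so a subject with less boundary
tissue than the control population scores negative. Voxels where the
control SD is at or below a floor (default 1e-6 — e.g. where no control has
any boundary) are excluded from the valid mask and assigned z = 0; a
standardization by a near-zero SD would be numerically meaningless there.
Controls are by default scored against the model that includes them, which
makes the control cohort self-normalize exactly (voxelwise mean 0, sample
SD 1 — an algebraic identity the tests assert to 1e-10); a leave-one-out
flag (`loo`) provides the unbiased variant, at the cost of that identity.

Smoothing is a separable Gaussian parameterized by FWHM
(σ = FWHM/(2√(2 ln 2)); 8 mm FWHM at 1 mm voxels is σ ≈ 3.3973 voxels),
truncated at 4σ, renormalized, with reflective boundary handling so
constants are preserved exactly. It is applied to gwBZ and gwBTV maps
after z-scoring and before all statistics, ROI and voxel alike — one
smoothing policy for every downstream consumer.

## Tissue fractions and TIV

Fractions are either passed through from files (mirroring an external
segmenter) or fitted by a univariate 3-component Gaussian-mixture EM on
in-mask intensities. The EM uses deterministic quantile initialisation
(means at the 1/6, 3/6, 5/6 quantiles), free means/variances/weights, and
exposes its per-iteration log-likelihood trace, which is non-decreasing by
construction. Components map to tissues by ascending mean — CSF < GM < WM,
the T1 contrast ordering. Posterior responsibilities are read as
partial-volume fractions. No spatial priors, bias-field model or "other"
class is fitted; fractions are normalized over the three tissues. TIV is
the sum of all tissue fractions times the voxel volume, in cm³.

## Phantoms and cohorts

The phantom is a nested-ellipsoid brain: WM core (default spherical
semi-axes 12 mm), GM shell (4 mm), CSF surround (3 mm), on a 40³ grid of
1 mm voxels. Partial-volume fractions are computed by supersampled
ellipsoid membership (default 3³ subvoxels; the WM volume estimate
converges monotonically toward the analytic ellipsoid volume as the factor
grows). Intensity is the fraction-weighted mixture of nominal CSF/GM/WM
levels 40/100/160.

Disease enters through four knobs: `contrast_scale` multiplies the WM−GM
intensity gap (the degraded gray level is I_WM − c·(I_WM − I_GM)); a
geometric Gaussian blur of the noiseless image; GM-shell atrophy (the
vacated shell becomes CSF, the outer surface staying fixed); and additive
Gaussian noise, seeded last. Noise is Gaussian rather than Rician for
simplicity — the pipeline consumes relative intensities only, where the
low-SNR Rician bias regime is not exercised. Ground-truth fractions are the
unblurred geometric ones, so segmentation recovery is measured against
geometry rather than against the degraded image.

Default study conditions: contrast 1.0/0.8/0.6 for CN/MCI/AD with a 0.05
between-subject SD, atrophy 0/0.3/0.6 mm, noise SD 2, and a **constant**
0.3 mm blur across groups. The band between the two thresholds provably
narrows as the gray-white gap shrinks, so contrast collapse carries the
disease ordering; blur, by widening the apparent interface, *raises* band
occupancy and has no monotone relation to boundary integrity, so letting it
vary by group would confound the effect the phantoms are built to plant.
Covariates: age ~ N(71.8, 4.8²)/N(72.6, 5.1²)/N(73.6, 7.7²) per group
(typical memory-clinic cohorts, entering only the subject table, never the
geometry, so covariate adjustment is testable in isolation); cognition
K-MMSE = 27.4 − 20·(1 − contrast) + N(0, 2²), clipped to [0, 30], giving
control means near 27 and dementia means near 19; CDR fixed at 0/0.5/1. A
per-subject global scale jitter (SD 3%, clipped to ±6%) makes TIV vary so
the intercept+TIV design is full rank. The toy atlas has three ROIs tied to
the nominal geometry: a ±2 mm boundary shell around the GM/WM interface,
the remaining GM shell, and the remaining WM core.

What the phantoms do **not** emulate: cortical folding, regional
heterogeneity, registration error, bias fields, Rician noise, or any
calibrated clinical effect size — the degradation magnitudes are free
parameters. Passing tests therefore demonstrate internal correctness and
direction-of-effect recovery, not clinical performance.

## Statistics

ANCOVA is an OLS fit of y ~ intercept + two group indicators + covariates;
the group effect is the partial F-test of the indicator block (F clamped to
0 when a saturated covariate fit leaves only floating-point residual).
Post-hoc pairwise comparisons are contrasts within the full model with
Bonferroni ×3 capped at 1. Partial correlation residualizes both variables
on [intercept + covariates] and tests the residual Pearson r with
df = n − 2 − q. Voxelwise GLMs fit the same designs at every in-mask voxel
(F for the group block, t for a single slope); FDR is Benjamini–Hochberg
over the analysis mask only — background voxels would dilute the rank —
followed by cluster-extent filtering under 18-connectivity (faces+edges;
6 and 26 available via a flag), default minimum 100 contiguous voxels.

Classification fits unpenalized logistic regressions of boundary measures
alone or combined with K-MMSE and CDR (CDR entered numerically although
ordinal), per group pair. ROC uses trapezoidal AUC (equal to the
tie-corrected Mann–Whitney statistic), a DeLong variance for the test
against AUC = 0.5, and reports sensitivity/specificity at the
Youden-J-maximizing threshold, ties broken toward the lowest threshold.
Perfect separation is flagged; the AUC, being invariant to monotone
transforms of the scores, is still reported from the final iterate.

## Problem sizes and determinism

The shipped analyses use 40³ grids and cohorts of 10 per group (5 per group
for the demo pipeline), sizes at which every stage runs in seconds while
all geometric and statistical properties under test are already stable.
The null-calibration simulation uses 500 replicates at n = 60; the binormal
AUC check uses 200 cases and 200 controls. All randomness flows from one
root seed through `numpy.random.SeedSequence` spawns, volumes are written
as uncompressed NIfTI, and tables with fixed float formatting, so a rerun
with the same configuration reproduces every artifact bit-for-bit.

## Known limitations

- The ellipsoid "distance" used for the atlas shell offsets semi-axes, which
  is exact for spheres (the default) and approximate for eccentric
  ellipsoids.
- The alternative gwBTV reading — convolving (f_GM+f_WM)·gwBB rather than
  the indicator — is not implemented; the indicator convolution is the
  canonical output.
- Normative models carry no covariate adjustment (no age-regressed norms).
- Voxel inference is parametric (F/t with BH-FDR); no permutation option.
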