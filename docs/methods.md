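# Methods

`mousefc` re-creates, end to end, a seed-based resting-state fMRI (rs-fMRI)
connectome analysis of three mouse cohorts — healthy controls, an
IDUA-deficient lysosomal-disease model ("mutant"), and mutants treated by
gene therapy — together with the downstream classifier and group
statistics.  Because the package must be testable without any scanner
data, the study population itself is synthetic: a generator produces the
atlas, the BOLD runs and the assay tables under the published study
conditions, and every analysis stage is exercised against them.

## Synthetic cohorts

**Atlas.**  The brain is an ellipsoidal mask inside the acquisition grid
(default 96 x 48 x 12 voxels of 0.25 x 0.25 x 0.5 mm, one voxel of air
margin per face so that simulated motion cannot push brain off the grid).
The mask is tiled into 235 regions: 117 bilateral pairs grown by seeded
Voronoi tessellation on the left half and mirrored to the right, plus one
midline region.  Voronoi cells restricted to a convex mask are
intersections of convex sets, hence connected.  Regions carry acronyms,
names, hemispheres and an anatomical family (isocortex, hippocampus,
thalamus, ...); the three seed regions of the analysis — anterior
cingulate (ACA), Ammon's horn (CA), mediodorsal thalamus (MD) — are always
present.

**Correlation templates.**  Each cohort has a target R x R population
correlation matrix.  Network blocks are the anatomical families; block k
receives a within-block correlation `scale * w_k` with fixed weights `w_k`
spread linearly over [0.75, 1.25] so that block strengths are
heterogeneous.  The control scale is set in closed form so that the
thresholded global connectivity strength of the template (mean of pairs
strictly above r = 0.15) equals 0.23; the treated template is calibrated
the same way to 0.25 over its restored blocks.  The mutant template is not
calibrated: limbic-family (hippocampus, thalamus) and interhemispheric
links are scaled by the attenuation factor (default 0.4) and all other
within-network links by the milder (1 + 0.4)/2 = 0.7, echoing the
predominantly limbic and interhemispheric connectivity loss of the disease
model.  In the treated cohort a fraction `restored_fraction` (default
0.95) of blocks is restored; the remainder — taken from the limbic
families first — stays at the mutant level ("unrestored" pairs).  Treated
calibration is independent of control because a multiplicative restoration
of control correlations could never exceed the control strength, while the
treated cohort's published strength (0.25) sits above control (0.23).
Non-PSD matrices arising from heterogeneous blocks are repaired by
clipping negative eigenvalues at zero and rescaling the diagonal to one;
templates must pass an eigenvalue floor of -1e-10 after repair.

**BOLD runs.**  Latent region signals are multivariate Gaussian with
covariance equal to the template (Cholesky factorization of the template
plus 1e-9 jitter), T = 310 volumes at TR = 1 s.  Every voxel carries its
region's latent signal (SD 1) plus i.i.d. white noise (default SD 1) on
top of a static baseline (about 100 units) that combines a smooth
large-scale intensity profile with mild per-region contrast — the
long-range gradients are what make intensity-based registration
well-posed.  Optional corruptions: Legendre-polynomial drift (shared
temporal shape, per-voxel gain) and rigid motion (explicit per-volume
parameters or a random walk), with injected motion recorded as ground
truth on the volume.  With the default noise the voxel-level seed
correlations are attenuated by a factor ~1/sqrt(2) relative to the
template, while region-mean correlations are nearly unattenuated because
each region averages ~100 voxels.

**Cohort design and assays.**  The default design has 6 + 6 + 8 mice with
2-3 runs each, 45 runs in total (15 per cohort) — the sample size implied
by the published bagging arithmetic (80% of 45 = 36).  Assay tables
reproduce the published summaries: IDUA 8.3 +/- 0.2 (control), below
detection level (mutant, stored as a 9-value tie block at the floor),
141.3 +/- 4.9 nmol/h/mg (treated); GAG 8.2 +/- 0.4, 24.5 +/- 0.4 and
6.9 +/- 0.2 ug/mg.  Group SDs are reconstructed from the SEMs
(SD = SEM * sqrt(n)) with n = (9, 9, 8).  One integer master seed fans out
to named substreams (atlas / bold / assay / run index), so each component
is independently reproducible.

## Preprocessing

Realignment estimates six rigid parameters per volume by Powell
minimization of the smoothed, z-scored mean-squared intensity difference
against the reference (default: the mean volume, two passes; alternately a
volume index), resampling trilinearly; out-of-field voxels are filled with
the air intensity so borders do not bias the cost.  With a mean reference
the trace is re-expressed relative to the least-moved volume (small-angle
subtraction) so the reference entry is exactly zero.  Drift removal
regresses out either Legendre polynomials (order as given) or a
discrete-cosine high-pass basis (components below 0.01 Hz by default) per
voxel and re-adds the temporal mean; residuals are orthogonal to the
basis.  Atlas normalization estimates a 12-parameter affine to the
atlas-space reference image in three stages (Powell on
translations/rotations, Powell on all 12, coarse-to-fine Gauss-Newton
with cubic interpolation at the finest level), achieving ~0.1 voxel RMS
on synthetic ground truth; a warped-support overlap below 25% of the atlas
mask flags registration failure.  No spatial smoothing and no band-pass
beyond drift removal are applied.  Synthetic runs are generated in atlas
space, so the pipeline default skips preprocessing; it is enabled by
configuration when motion or drift are simulated.

## Connectome measures

Region time series are voxel means per label; seed maps are Pearson
correlations of one seed's series against every in-mask voxel (constant
voxels give NaN, never zero).  Seed maps are thresholded jointly on
magnitude (|r| >= 0.15) and on the uncorrected correlation p-value
(t transform with df = T - 2, two-sided, alpha = 0.05).  The
region-to-region matrix is the pairwise Pearson matrix; zero-variance
regions are flagged and NaN-ed.  The global functional connectivity
strength is the mean of upper-triangle entries strictly greater than 0.15
— negative and sub-threshold correlations do not contribute, and the
statistic is NaN when nothing qualifies.  Group inference operates on
Fisher-z transformed correlations (variance stabilization): one-sample t
against zero within cohorts, Welch t between cohorts, both voxelwise and
uncorrected; infinite t at zero-variance voxels is flagged and the p-value
floored at the smallest positive float.  Runs are averaged within subject
(z-scale) before group maps to avoid pseudo-replication.  Cohort-average
matrices are entrywise z-averages, back-transformed.

## Network classifier

Each seed map is segmented into cubic grids of 3x2x1, 6x4x2 and 12x8x4
voxels — sizes that tile the 96x48x12 matrix exactly (10512 features:
9216 + 1152 + 144); the feature is the mean of valid voxels per cube
(all-NaN cubes give 0 with a missingness flag), ordered resolution-major
and x-fastest.  The classifier is a multinomial logistic LASSO: it
maximizes the (summed) multinomial log-likelihood minus
lambda * sum|w| over internally standardized features.  The solver is a
partial-Newton coordinate descent of the glmnet family, written here and
accelerated with numba: outer iterations build the per-class quadratic
approximation (working response, probability-based weights floored at
1e-5), an inner weighted-lasso coordinate descent soft-thresholds over
the active set with full verification passes, and convergence is declared
when no linear predictor moves by more than the tolerance.  On small
problems its penalized objective agrees with an independent solver to
~1e-12; at the study's 36 x 10512 size one fit takes ~0.1 s, which is
what makes bagged ensembles with per-subsample cross-validation feasible
on one CPU.  A one-vs-rest mode is available by configuration.

Bagging draws B stratified subsamples of size round(0.8 n) without
replacement (with-replacement available), re-selects lambda per subsample
by stratified cross-validated deviance over a warm-started log-spaced grid
anchored at the data's lambda_max (ties resolve to the sparser model), and
fits one model each.  The ensemble records per-feature selection
frequencies and the coefficient-averaged model; prediction averages the
member softmax probabilities, and an out-of-bag variant scores each sample
only with models that never saw it (used for null calibration).  The
library default is B = 1000 with 5-fold CV, as in the study; the pipeline
and the acceptance run use the desk-scale configuration B = 200, 2-fold
CV over a 3-point lambda grid at tolerance 1e-3, which leaves the
strong-separation results unchanged (all in-sample AUCs reach 100%) while
keeping the three-seed ensemble under ten minutes on one CPU.  Per-seed
ensembles are combined by averaging their predicted probabilities.  ROC
analysis is one-vs-rest per class; AUC is the Mann-Whitney rank statistic
with half-credit ties, with curve points for plotting.  Significant
predictor networks are features selected in at least half the members
whose best pairwise Welch t-test across cohorts has p < 0.001
(uncorrected, per the study's convention); cubes map to regions by
majority voxel label.

## Cohort statistics

One-way ANOVA uses the classical pooled-variance table with df
(k-1, N-k); the F tail is checked against the closed form
(1 + 2F/df2)^(-df2/2) at df1 = 2.  Kruskal-Wallis uses mid-rank ties and
the standard correction divisor 1 - sum(t^3 - t)/(N^3 - N) — with the
9-value below-detection tie block and groups (9, 9, 8) this reproduces
the published chi-squared of 23.2 exactly.  An assumption gate (Shapiro-
Wilk per group, Levene across groups, both at 0.05; zero-variance or
n < 3 groups route directly) chooses between the two and logs its
reasons.  Note the gate's joint false-alarm rate on normal data is
1 - 0.95^4 ~ 19%.  Post hoc contrasts are Dunn's rank-based z-tests with
pooled tie-corrected variance (companion to Kruskal-Wallis) or pairwise
Welch t-tests; no multiplicity correction, matching the study's
uncorrected reporting.  At sizes (9, 9, 8) the most extreme possible
rank separation yields p ~ 0.013 for adjacent pairs — an analytic floor
worth knowing when interpreting rank-based post hocs at these n.  The
biochemistry-connectivity link is the Pearson correlation of the three
cohort means of GAG against the three cohort means of global strength
(R^2 ~ 0.99, negative r, on the published values).

## What the synthetic data do and do not show

The generator reproduces the study's *conditions* — sample sizes, printed
group means/SEMs, tie structure, correlation-strength targets, grid
geometry — but its BOLD model is deliberately idealized: Gaussian latent
signals with exact block covariance, white voxel noise, no hemodynamic
response, no physiological (cardiac/respiratory) noise, no susceptibility
artifacts, and cohort differences that are step-like across anatomical
families rather than graded.  Classification is therefore
strong-separation by construction, and passing the AUC reproduction shows
that the feature extraction, penalized fitting, bagging and combination
machinery is correct — not that real mutant mice are separable at these
accuracies.  Likewise the global-strength reproduction shows the
statistic and its calibration behave as designed under sampling noise at
T = 310 (the run-level estimate carries a small upward bias, ~0.005-0.01,
from threshold truncation of near-threshold entries; it stays inside the
published +/- 0.02 band).

## Numerical choices and degenerate inputs

Fisher z uses |r| clipped at 1 - 1e-7; p-values are floored at the
smallest positive float; correlation of a constant series is NaN, a
constant seed is an error.  The LASSO treats lambda = 0 as 1e-10 with an
iteration cap (the separable-data optimum is at infinity); standardization
guards zero-variance features with unit scale.  Template repair clips
eigenvalues; simulation refuses templates below an eigenvalue floor of
-1e-8.  Registration degenerate cases (all-zero volumes) are flagged and
skipped rather than fitted.  Assay draws are clipped to positive values;
zero SEM produces exact group means.  All tie-breaks are deterministic
(first/larger-lambda/lowest-index conventions noted at each site).
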