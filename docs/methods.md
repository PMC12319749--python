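# Methods

## Scope

`caudconn` reimplements, as a testable pipeline, an analysis of age-related
dedifferentiation of caudate-cortical functional connectivity and its
dopaminergic correlates: voxel-wise winner-take-all parcellation of
striatal voxels onto cortical networks, sphere-ROI seed connectivity during
rest and a blocked n-back task, simplified-reference-tissue-model (SRTM)
estimation of D1 receptor binding potential from PET time-activity curves,
and an inferential layer of mixed models, covariate-adjusted regressions,
BCa-bootstrap mediation, a PCA memory composite, and Holm-Bonferroni
correction.  Human imaging data of this kind are not redistributable, so
the package ships a first-class synthetic-data generator that emulates the
statistical structure of such a study; every analysis stage is validated
against the generator's planted ground truth.

## The synthetic cohort

`generate_subject_table` draws `n` subjects (default 180) with ages
stratified-uniform on 20-79 years and age groups young (20-39), middle
(40-59), old (60-79).  Standardized binding potential follows
`bp_z = a * age_z + noise` and the latent connectivity differentiation
`d_z = b * bp_z + c' * age_z + noise`, so the planted indirect effect of
age on differentiation through binding is exactly `a * b`.  Defaults
(rest: a = -0.55, b = 0.25, c' = -0.18; task via prefrontal binding:
a = -0.60, b = 0.17, c' = -0.24) give a total standardized age effect of
~-0.32 and a mediated share of ~44% (rest) / ~28% (task), realistic for a
lifespan D1-receptor cohort.  Raw differentiation is
`0.10 + 0.18 * d_z` Fisher-z units at rest, so group means run from ~0.17
(young) to ~0.03 (old): a clear FPN preference in the young that nearly
vanishes in the old.  Binding potentials are mapped to plausible scales
(caudate 2.0 +/- 0.45, prefrontal 0.45 +/- 0.12, clipped at zero).

### BOLD runs

Latent network signals are white noise hard-masked in the frequency domain
to the 0.009-0.09 Hz analysis band and QR-orthonormalized, so sample
correlations between latents are exactly zero and the analysis bandpass is
approximately idempotent on clean signal.  Cortical voxels carry their own
network's latent plus white measurement noise (sd 0.3).  Striatal voxels
carry a correlation-weighted mix of latents: the weight vector *is* the
planted voxel-network correlation.  The default profile plants a
medial-lateral gradient (FPN correlation 0.60 - 0.40 p, DMN
0.20 + 0.40 p for medial position p, limbic-like band at the medial end,
0.08 to all other networks) with age slopes of -/+ 0.0022 per year on the
FPN/DMN weights, so the FPN/DMN boundary moves laterally with age and the
FPN-allocated territory shrinks across age groups while DMN territory
grows.  The gradient is deliberately steep: the winner margin of every
voxel plane stays clear of the group-map decision noise (~0.025 z at 20
subjects/group, 350 volumes) at each group's boundary position, so
assignment errors measure real failures rather than planted ambiguity.

Voxels inside the seed box instead realise Fisher-z correlations
`0.35 +/- d/2` with the FPN/DMN latents, where `d` is the subject's planted
differentiation; their shared residual is a band-limited signal orthogonal
to the latents, so the seed-ROI mean reproduces the planted
differentiation to machine precision in the noiseless limit.  All other
striatal voxels receive per-voxel white residuals orthogonalized exactly
against the latents — a shared residual would constitute a striatum-wide
common component that nuisance regression and filtering turn into
systematic margin distortion.

Two nuisance components make the cleaning stage meaningful: a volume-wide
global fluctuation (sd 2.0, the component the global-signal regressor
exists to remove — without it the global mean is dominated by the sum of
network latents and its regression destroys planted structure) and a
motion artifact proportional to framewise displacement added to brain
voxels.  Motion traces are bounded random walks rescaled so realized mean
FD matches the subject's target (lognormal, median ~0.11 mm, increasing
with age), with ~2 injected translation spikes per run (0.6 mm) at
recorded volumes.

Task runs use the blocked design: 6 lead-in rest volumes, then 27 blocks
(9 per load, order randomized once and fixed across subjects) of 1 cue
volume, 10 task volumes (10 stimuli x 2 s), and 1 rest volume — 330
volumes at TR 2 s.  The striatal-FPN coupling is multiplied by the load
gain (defaults 1.0 / 1.3 / 1.6 for 1/2/3-back; off-task volumes at 0.5,
reflecting between-block disengagement of task-positive coupling), and the
effective gain series is delayed by 4 s, so the analysis-side lag shift of
`round(4 s / TR) = 2` volumes realigns it exactly.  A pure delay (not an
HRF convolution) keeps the generator invertible by the stated analysis.

### PET and behaviour

`generate_tac` produces a gamma-variate reference curve
(`A t^1.2 exp(-t/8)` minutes, peak ~30 units near 10 min) and the SRTM
forward solution for the target region, frame-averaged over the 60-min
schedule (6x10, 6x20, 6x40, 9x60, 22x120 s).  Frame noise has sd
`noise_scale * sqrt(activity / duration_min)` on the target curve only;
the reference is treated as the estimator's known input so that fits
measure estimator properties, not input noise.  The default
`noise_scale = 0.15` represents a well-counted regional TAC (~2% noise at
the curve peak).

`generate_behavior` adds six bounded integer memory scores (maxima 32, 20,
24, 48, 108, 30).  A single latent factor declines with age
(standardized -0.45), carries the planted connectivity link (0.25, with a
0.15 age interaction so the connectivity-memory association strengthens
with age), and loads 0.7 on each task, which puts the expected first
principal component share near 57% before integer rounding and clamping.

## Analysis stages

**Preprocessing.**  Framewise displacement in the Power formulation (sum
of absolute backward differences, rotations as arc length on a 50 mm
sphere; Jenkinson's RMS formulation selectable).  Confounds: mean CSF, WM
and global signals, the 24-parameter motion expansion (parameters, lags,
and both squared), and one one-hot spike column per volume with
FD > 0.2 mm (a single shared binary column is selectable; spike columns
are the standard realization and equivalent to censoring).  Voxel-wise OLS
residualization, then a zero-phase 2nd-order Butterworth bandpass
(0.009-0.09 Hz), then isotropic Gaussian smoothing
(sigma = FWHM / 2.3548).  QC exclusions are strict inequalities: mean
FD > 0.30 mm, any task accuracy not above 50%, values beyond 3.29 SD of
the pre-exclusion mean.  Note the bandpass is *not* 1%-idempotent over its
full passband: a 2nd-order Butterworth is -3 dB at the band edges by
definition; idempotence to <1% holds in the flat region (~0.02-0.045 Hz),
which is where the generator's latent power lives in expectation.

**Parcellation.**  Per-subject Pearson correlation of every striatal voxel
with every cortical voxel over all retained volumes, Fisher z-transformed
(|r| clipped to 1 - 1e-7), averaged within age group; each striatal voxel
takes the modal network label among its top-25 cortical voxels by
group-mean z.  Ties at the 25th rank resolve by ascending voxel index
(stable sort); network-vote ties by larger summed z, then lower label
index; all tie events are logged.  Allocation fractions and cross-group
retention/redistribution tables follow.

**Connectivity.**  ROIs are spheres at mm coordinates (packaged defaults:
bilateral 6 mm spheres for the caudate seed at +/-12, 10, 8, three FPN and
three DMN cortical targets, and an optional caudate DMN seed at
+/-8, 10, 1); bilateral ROIs pool both hemispheres into one time series.
Connectivity is the mean Fisher z between the seed mean series and each
target (per-target correlation, then within-network average);
differentiation = z_FPN - z_DMN.  Task analysis selects each load's
volumes, shifts them 2 volumes later (4 s lag at TR 2 s), drops indices
past the run end, excludes cue/rest volumes, and pools blocks into one
estimate (minimum 30 volumes).  Two documented alternatives are
selectable: unilateral sphere extraction (`hemisphere='left'/'right'`)
for analyses that average two unilateral correlations instead of pooling
one bilateral series, and per-block correlation with z-averaging
(`block_average=True`); the defaults pool, maximizing volumes per
estimate.

**SRTM.**  Forward model
`C_T = R1 C_R + (k2 - R1 k2 / (1+BP)) [C_R (x) exp(-k2 t / (1+BP))]` with
trapezoidal convolution on a uniform 0.5 s grid (FFT-based; halving the
step changes curves by <0.05%).  Fitting reconstructs the continuous
reference from frame averages by average-preserving monotone-cubic
interpolation (knots at frame midpoints, iteratively corrected so the
curve's frame averages reproduce the observed frames — plain midpoint
interpolation leaves ~3% k2 bias), then runs bounded weighted least
squares (R1 in [0.1, 3], k2 in [0.01, 1]/min, BP in [0, 10]; weights =
frame duration by default) from three starts spanning slow/typical/fast
kinetics, keeping the best converged solution.  A basis-function backend
(`method='basis'`: log-spaced grid over the washout rate
lam = k2/(1+BP), weighted linear solve for R1 and the convolution
coefficient at each grid point) is available with the same contract.
Time is minutes internally; schedules are read in seconds.

**Statistics.**  OLS and random-intercept mixed models via statsmodels,
with per-model z-scoring of the outcome and continuous predictors when
standardized coefficients are requested.  Mixed-model fixed-effect
p-values are Wald z (recorded in the output; Satterthwaite degrees of
freedom are not available in this backend — the calibration contract is
what the tests check).  Likelihood-ratio selection compares plain-ML fits;
interactions are retained at p < 0.05.  Mediation uses nonparametric case
resampling at the subject level (5,000 draws by default) with
bias-corrected accelerated intervals: bias term z0 from the share of
bootstrap draws below the point estimate (ties counted half), acceleration
from jackknife skewness.  For linear models with a shared covariate set
the identity `total = direct + indirect` holds to numerical precision and
is asserted.  Proportion mediated is indirect / (indirect + direct),
flagged when outside [0, 1].  The memory composite is the first
eigenvector of the task correlation matrix, sign-fixed to positive mean
loading.  Holm correction is the standard step-down procedure with
monotonicity enforcement; rejection uses adjusted p < alpha.

## Study drivers and problem sizes

The cohort-level studies (`caudconn.studies`) run the full chain at
toy-grid scale: an 18x18x18 grid of 3 mm voxels, a 2-plane cortical slab
split into 7 strips of 72 voxels, and a 4x12x4 striatal box (192 voxels).
The parcellation-recovery study uses 20 seeds x ~60 subjects (three age
groups) at 350 rest volumes; the lag/gain study 48 noiseless subjects; the
SRTM studies a 3x3x3 parameter grid plus 100 noisy replicates; LRT
calibration 1,000 null replicates at n = 180; mediation coverage 300
replicates at n = 500 with 2,000 bootstrap draws (BCa intervals for the
product of coefficients undercover at n ~ 100-200, in line with the
bootstrap literature; n = 500 restores nominal coverage).  These sizes
were chosen once as the package's standard study conditions.

Two driver-level choices: the recovery studies disable spatial smoothing,
because on a toy grid with 2-voxel network strips a 6 mm kernel mixes
strips and tests the smoother rather than the parcellation (the disk
pipeline applies the standard 6 mm default in the stated order); and the
slope-recovery check aggregates over the 20 seeds, because with a
realistic standardized age effect (~-0.32) a single-cohort (n~60) slope
estimate flips sign by sampling noise in a non-negligible fraction of
seeds.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: band-limited
network signals, age-dependent coupling geometry, subject-level mediation
paths, load-gain modulation at a fixed hemodynamic delay, SRTM-consistent
TACs, motion with spikes, and a latent-factor memory battery.  It does not
emulate scanner physics, spatial autocorrelation of noise, an HRF shape
(the delay is a pure shift), physiological noise spectra, PET count
statistics beyond the stated variance model, or anatomical geometry
(atlases are toy volumes; the interface accepts real label atlases
verbatim).  Passing tests therefore demonstrate the *procedures* recover
planted structure under the stated assumptions — not performance on real
scanner data.

## Known limitations

- Winner-take-all margins near a moving FPN/DMN boundary are inherently
  ambiguous; the default profile avoids planting voxels inside the
  decision-noise window, so accuracy numbers do not probe that regime.
- The mixed-model backend provides Wald rather than Satterthwaite
  p-values; at the replication counts used here the difference is
  negligible for calibration but individual p-values differ slightly from
  an lmerTest-based implementation.
- The medial-caudate DMN-seed variant backed by an external parcel is
  supported only as a sphere ROI; serial multiple mediation and gPPI task
  connectivity are out of scope.
- `fit_srtm` treats the reference TAC as noise-free input; reference noise
  propagates into parameter bias that is not modelled.
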