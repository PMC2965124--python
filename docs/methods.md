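# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would otherwise have to reverse-engineer.

## Diffusion model and tensor estimation

Each voxel's diffusion is modelled by a single 3×3 symmetric positive-definite
tensor `D` (mm²/s).  The signal along unit gradient `gᵢ` at b-value `bᵢ` is
`Sᵢ = S0 · exp(−bᵢ gᵢᵀ D gᵢ)`.  Estimation is ordinary least squares on log
signals, which is linear in `(log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`.  OLS was
chosen over weighted or nonlinear fitters because it is exact for noise-free
data (the round-trip tests demand recovery to 1e-6) and is the common default
for single-shell acquisitions; it is mildly noise-biased at low SNR, which the
SNR-20 tolerance (mean FA error < 0.05) absorbs.

Numerical guards: weighted signals exceeding the voxel's mean b=0 signal are
clamped to it (log attenuation ≤ 0), all signals are floored to a tiny
positive value before the log, voxels with non-positive mean b=0 signal are
flagged invalid, and a gradient scheme whose 6-column quadratic-form design
has rank < 6 is rejected naming the rank.  Eigenvalues are clamped at zero
before FA; an all-zero tensor is defined to have FA 0.

The default acquisition is 30 quasi-uniform directions (golden-angle spiral
on the sphere) at b = 1000 s/mm² plus 5 unweighted scans, 2 mm isotropic
voxels — a standard clinical single-shell scheme.

## FACT tractography

Deterministic fibre assignment by continuous tracking: within each voxel the
streamline direction is that voxel's principal eigenvector, sign-aligned with
the incoming direction; the streamline advances in a straight segment to the
voxel boundary (plus 1e-4 voxel, to avoid stalling on a face) and terminates
on FA below the stop threshold, a turn sharper than the maximum angle, or
grid exit.  Seeds default to every voxel at or above the seeding FA
threshold, one seed at the voxel center, launched in both eigenvector signs.

Defaults — seed FA 0.2, stop FA 0.2, maximum turn 45°, minimum length
10 mm — are the field-standard operating point for adult white matter; all
are configurable.  Two implementation details are deliberate:

- *Endpoint retraction.*  On termination the endpoint is retracted from the
  exit face to the center of the last valid voxel.  Trilinear sampling at a
  face shared with a sub-threshold voxel would average ~50% out-of-mask
  signal into the tract profile's endpoints; retraction keeps every recorded
  point inside the tracking mask at the cost of up to half a voxel of length.
- *Directions live in world space*; steps are converted through the affine,
  so anisotropic voxels and off-diagonal affines are handled uniformly.

## Tract selection and along-tract FA profiles

A tract is the subset of streamlines with at least one point whose nearest
voxel lies in each of two ROI masks (e.g. precentral gyrus and brainstem for
the CST; left and right precentral gyri for the callosal fibres).  Selection
is idempotent and order-independent.

For profiling, each streamline is resampled to `n_points` (default 100)
equidistant arc-length positions and oriented so the end nearer the first
ROI's centroid is t = 0 (cortex end, by convention); FA is read by trilinear
interpolation and averaged across streamlines per position.  This
common-normalized-axis averaging deliberately replaces full inter-subject
tract registration: profiles from different subjects or phantoms are compared
position-wise on t ∈ [0, 1].  "Rostral", "middle" and "caudal" are the first,
second and last thirds of the cortex→brainstem profile — the tract-level
granularity at which the rostral-deficit pattern is assessed.

## Tube phantom

The DWI generator plants a finite cylinder (default radius 4 mm) along a
straight or user-supplied centerline in a 16×16×36 grid of 2 mm voxels.
In-tube voxels receive prolate tensors with the principal axis tangent to the
centerline; the planted FA follows a profile over normalized arc position
(a flat 0.7 for controls; `0.7 − 0.2·(1−t)`, i.e. 0.5 at the cortex end, for
the patient condition).  For an axially symmetric tensor with eigenvalues
`m(1+2a), m(1−a), m(1−a)` (mean diffusivity `m` = 0.7e-3 mm²/s), FA inverts
in closed form to `a = FA/√(3 − 2FA²)`, so planted FA is exact by
construction.  The nearest-point distance test would add spherical caps
beyond the centerline ends; these are cut (axial-projection test) so the
planted profile spans the entire tract.

Background voxels are "isotropic at background FA" in the operational sense:
a truly isotropic tensor has FA = 0, so a positive background FA (default
0.05) is realised as mildly prolate tensors with seeded random orientation,
making the noise-free fit recover the background FA exactly; background 0
gives exactly isotropic tensors.  Noise, when requested, is Rician — the
magnitude of the complex Gaussian-corrupted signal, as in scanner magnitude
images — and zero noise reproduces the model exactly.  ROI masks cover the
tube's two end slabs (default 5 mm deep) plus a third mask mirrored through
the mid-sagittal plane standing in for the contralateral cortex.

Not emulated: eddy currents, susceptibility distortion, partial-volume mixing
at the tube surface, and crossing fibres.  Passing the phantom suite
therefore certifies the estimator/tracker/profiler chain, not robustness to
those acquisition artifacts.

## BOLD generator

Motor-network BOLD is synthesised by low-pass filtering Gaussian innovations
below 0.1 Hz (order-2 Butterworth, zero-phase), empirically whitening them,
and mixing through an eigen-factor of the target correlation matrix, then
adding white measurement noise (default 0.1 of signal SD).  Because of the
whitening step the sample correlation of the noise-free signals equals the
target exactly at any series length; measurement noise attenuates it by
~1/(1+f²).  Defaults emulate an 8-minute acquisition at 0.5 s sampling
(960 samples) over six nodes: left/right precentral, supplementary motor and
premotor cortex — a minimal motor network; the node set is configurable.
Positive semi-definite targets with zero eigenvalues (duplicated nodes) are
allowed; meaningfully negative eigenvalues are rejected naming the value.

The generator does not emulate haemodynamic response shape, scanner drift,
motion, or physiological (cardiac/respiratory) aliasing; the short sampling
interval of the emulated acquisition is what justifies ignoring the latter.

## Functional graphs

Graphs are binarized at `r > threshold` using positive correlations only:
the operating thresholds (0.30 for γ, 0.40 for connection counts) are plain
correlation values, and the treatment of anticorrelations in resting-state
fMRI is contested, so they are excluded rather than folded in by magnitude.
Both thresholds are applied by default in the pipeline.

Clustering uses the Watts–Strogatz convention: `Cᵢ = 0` for degree < 2, and
the network `C` averages over all nodes (a flag excludes low-degree nodes
instead).  γ normalizes `C` by the mean clustering of 100 degree-preserving
Maslov–Sneppen surrogates (10×E swap attempts each, seeded); surrogates with
zero mean clustering make γ an explicit error rather than infinity.  Random
graphs calibrate to γ ≈ 1 and ring lattices to γ ≫ 1, which is what makes γ
interpretable as "local connectedness in excess of the degree sequence".

## Cohorts and statistics

Cohorts are two groups of 12 (ages ~49 ± 10, clipped to 33–65).  Cortical
thickness is generated per region of the 34-region-per-hemisphere
Desikan–Killiany parcellation (generic mean 2.5 mm, precentral 2.68 mm,
between-subject SD 0.1 mm); patients lose 0.09 mm bilaterally on the
precentral gyrus.  ALSFRS-R is uniform on [30, 46] and disease duration
uniform on [7, 30] months, reproducing the published patient ranges; the
progression rate `(48 − ALSFRS-R)/duration` is deliberately *not* stored by
the generator — the stats stage derives it, so the planted γ relation
(γ = 1.6 + 0.6·rate + N(0, 0.12)) is only recoverable through the package's
own derivation.  Controls draw γ around the same mean so the groups do not
differ in γ, matching the intended phenomenon: organisation preserved,
progression-linked.  Tract-FA summaries carry a 0.05 patient deficit.  The
slope 0.6 and noise 0.12 were fixed from the published patient
progression-rate spread (SD ≈ 0.4 points/month) to give a planted
correlation around 0.9 — a clearly detectable but noise-limited effect at
n = 12.

Group comparisons fit `outcome ~ group + covariates` by OLS; with no
covariates this is algebraically the pooled two-sample t-test, which is also
available directly from printed summary statistics (`summary_ttest`, pooled
by default, Welch by flag).  Partial correlations residualize both variables
on the covariates (with intercept) and use n − 2 − #covariates degrees of
freedom.  All tests are two-sided at α = 0.05 with no multiplicity
correction, matching a single-pre-registered-region strategy; a Bonferroni
flag exists for the report table.

The report's pre-registered pairs and their covariates: precentral thickness
(contralateral to the clinically most affected side, a synthetic per-patient
field, since the affected side is not derivable from imaging) vs ALSFRS-R and
progression rate, adjusted for age and whole-brain thickness; rostral-CST and
callosal FA vs both, unadjusted (the corresponding published analysis states
no adjustment); γ vs both, adjusted for the number of connections and age;
and callosal FA vs interhemispheric connection count across all subjects.

## Pipeline and reproducibility

A single YAML config plus one mandatory global seed drives the full run.
Per-stage seeds are derived by hashing the stage name with the global seed
(CRC-32, reduced below 2³¹), so adding or reordering stages does not shift
any other stage's randomness.  Outputs are plain CSV/JSON; the run log keeps
level and message only (no timestamps), and the summary carries a SHA-256
provenance hash of the scientific parameters, so identical config + seed
yield byte-identical output trees — asserted by test and acceptance script.

Problem sizes throughout (16×16×36 phantom grids, 960-sample BOLD, 100
surrogates, 100–200 simulated cohorts) are the package's demonstration
scale: large enough that every planted effect is measured with comfortable
Monte-Carlo margin, small enough that the full suite runs in minutes on one
core.

## Known limitations

- Single-tensor model and deterministic tracking: crossing-fibre geometries
  are out of scope, and the callosal/CST crossing region of real data is
  exactly where that matters.
- The phantom certifies recovery, not robustness: no distortion, motion or
  partial-volume effects are simulated.
- Whole-brain surface reconstruction is upstream of this package; cortical
  thickness enters as region-level tables.
- γ on very sparse graphs (few triangles) is noisy and can be undefined;
  the package raises rather than returning an arbitrary value.
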