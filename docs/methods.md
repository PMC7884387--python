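# Methods

This note records the models implemented, the assumptions and numerical
choices behind them, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one defensible convention
exists.

## Adjusted Z-scores (`dental_metrics`)

A single specimen x is compared to a comparative group summarised by its
mean X̄, sample standard deviation SD (n−1 denominator) and size n:

    z_adj = (x − X̄) / ( t_{1−α/2, n−1} · √( SD² · (1 + 1/n) ) ).

This is the deviation scaled by the half-width of the two-sided
100(1−α)% Student-t prediction interval for one new observation from a
normal population. Consequently |z_adj| ≤ 1 ⇔ x lies inside the group's
100(1−α)% prediction band, at every n; the classical Z-score has this
property only asymptotically. α defaults to 0.05 and is configurable.
Degenerate inputs: SD = 0 with x ≠ X̄ returns a signed infinity (the
specimen is categorically outside an exactly constant sample); n < 2 is
rejected because the t distribution with n−1 degrees of freedom does not
exist.

The formula assumes the comparative sample is approximately normal and
the summary statistics were computed with the n−1 denominator. Both
assumptions are carried through the synthetic comparative-sample
generator, so the Monte-Carlo coverage test (95% of fresh draws inside
the unit band, n ∈ {5, 10, 20, 50}, 100,000 replicates per n) checks the
construction itself, not robustness to non-normal groups.

Wear adjustment of the mesiodistal length is deliberately not
implemented: the wear-corrected length is accepted as an input variable,
and which variant was used is up to the caller to record.

`si_optional_checks` recomputes a specimen profile against an externally
supplied comparative-summary CSV and returns a "data absent" status
(`None`) when no such table exists; the comparative dental tables this
workflow is normally run against are not freely redistributable.

## Voxel tissue metrics (`tissue3d`)

Conventions: voxel grids are 0-based with isotropic physical voxels; a
voxel's volume is `voxel_size³` and its centre is `(index + 0.5) ·
voxel_size`. A voxel belongs to a half-space iff its centre does, with
centres exactly on a plane assigned to the side below it (along the
occlusally oriented normal). This makes every plane split exactly
conservative in voxel counts — the stem and branch volumes always sum to
the total root volume by construction, and cropping a slab in two pieces
reproduces the whole slab exactly.

*Cervical plane.* Total-least-squares fit (smallest principal axis of the
centred point cloud); collinear point sets are rejected. The normal is
oriented toward a declared occlusal direction.

*Lateral crown proportions.* After cropping between the cervical plane
and a parallel occlusal-basin plane: 3D LAET = lateral enamel volume /
EDJ surface area (mm), 3D LRET = 100 · LAET / (lateral dentine+pulp
volume)^⅓ (dimensionless). The LRET denominator is the lateral coronal
dentine-plus-pulp volume; this follows the usual relative-enamel-
thickness convention and is recorded here as an assumption.

*EDJ surface area.* Default estimator: marching-cubes isosurface of the
dentine+pulp body (after padding and a σ = 0.7-voxel Gaussian smoothing
of the binary mask, which suppresses the staircase area bias of a binary
isosurface without materially displacing the interface), keeping only
triangles whose outward side samples enamel. On a cylindrical-shell
phantom at voxel = radius/80 this recovers the analytic interface area
to well under 1%. A face-counting estimator with a configurable
correction factor (default 2/3, the isotropic-orientation staircase
correction) is available as `area_method="face_count"`; it is exact on
axis-aligned flat interfaces but biased by up to ~15% on curved ones,
which is why it is not the default.

*Bifurcation plane.* The interradicular level can be supplied in mm below
the cervix or located automatically: scanning voxel layers apically from
the cervical plane, the first layer whose root cross-section has ≥ 2
connected components (8-connectivity in-plane). The automatic rule
requires an axis-aligned cervical plane; oblique planes must pass an
explicit level. A root that never splits raises `BifurcationNotFound`
(VBI is undefined for a single-rooted tooth). VBI itself is
100·V_cervix/(V_cervix+V_branch), invariant under uniform scaling.

*HMH threshold.* The half-maximum-height rule for two-material grayscale
segmentation is the midpoint of the two material intensities. With
material means 30/170 and Gaussian noise SD 10 it misclassifies well
under 1% of voxels; the simplification relative to interactive
region-of-interest protocols is intentional (those are manual).

## Geometric morphometrics (`gmm`)

*Curve resampling.* Semilandmark curves are resampled to equal arc-length
spacing along the polyline (endpoints preserved). No bending-energy
sliding is performed: the workflow this implements uses fixed
equally-spaced semilandmarks, and inventing a sliding criterion would
change the shape space silently.

*GPA.* Iterative superimposition: centre, scale to unit centroid size,
rotate each configuration to the evolving consensus (SVD rotation with
the reflection branch excluded — anatomical configurations are
side-specific), consensus = mean of rotated configurations, until the
consensus moves < 1e-10. Centroid sizes are reported from the
pre-scaling configurations. Because GPA fixes shape only up to one
global rotation (the output rotates exactly with the orientation of the
first input), the converged configuration set is finally expressed on
the consensus' principal axes with a deterministic sign rule (cubed
projections sum positive; third axis completes a right-handed frame).
This makes the aligned coordinates and residuals themselves — not just
their invariants — reproducible to machine precision under arbitrary
rigid motions and scalings of the inputs.

*Ordinations.* PCA is the eigendecomposition of the residual covariance.
bgPCA takes the principal components of the g group-mean residual
vectors — unweighted by default, size-weighted behind a flag, since
either convention appears in practice — and projects all specimens onto
them (at most g−1 informative axes). CVA solves the generalized
eigenproblem B a = λ W a on the leading PCs, with axes normalized to
unit within-group variance; the number of PCs is chosen as the smallest
set explaining ≥ 90% of total variance (configurable), capped at the
within-group degrees of freedom n − g.

*Classification.* Mahalanobis distance to each group mean under the
pooled within-group covariance, ridge-regularized with λ = 1e-8 ·
trace/dim (configurable) because small samples with many variables make
singularity routine. Posteriors are the equal-prior Gaussian form
posterior_g ∝ exp(−d_g²/2); chi-square tail "typicality" probabilities
are reported alongside, since toolchains differ in which they print.
Ties are broken deterministically by group-name order and flagged.
Leave-one-out cross-validation re-estimates group means and ordination
axes per fold; the Procrustes alignment is computed once on the full
sample (standard practice; re-running GPA per fold changes results
negligibly at these sample sizes but is easy to add by refitting the
aligner per fold). Unknown specimens are aligned to the training
consensus by ordinary Procrustes (translation, unit scale, rotation) and
projected a posteriori; training scores are untouched.

bgPCA is known to manufacture apparent group separation when variables
outnumber specimens. The guard asserted in the tests: on a single
homogeneous population (150 variables, n = 30) with randomly permuted
labels, leave-one-out bgPCA accuracy must fall inside the 95% binomial
interval of chance — separation that survives cross-validation is the
only kind the package treats as meaningful.

*Allometry.* Per-axis ordinary least squares of ordination score on
centroid size, reporting slope, R² and the F-test p-value; constant
centroid size is rejected.

## Lithic analysis (`lithics`)

Indices follow the printed calliper definitions: elongation L/W,
proximal shape PW/MW, distal shape MW/DW, flattening MW/MT, and TCSA =
distal width × distal thickness (mm²). The conventional ½·width·
thickness TCSA variant is exposed separately as `tcsa_half` and never
substituted silently. Zero denominators yield missing values with a
warning rather than exceptions, so batch processing of museum tables
does not abort; missingness is handled complete-case per analysis with
exclusion counts reported (imputation would fabricate morphology).

Normalization is the rank-based ordered-quantile normal-scores
transform — the transform a best-normalizing tool most often selects for
strictly positive, skewed calliper data — with ranks mapped at
(r − 0.5)/n, ties averaged, monotone interpolation (with linear tail
extrapolation) for held-out rows, then exact centring/scaling on the
training column. Constant columns are dropped with a warning.
Categorical variables are carried as labels and excluded from PCA.

Assemblage comparison: convex-hull intersection-over-union in the
chosen two-axis score plane plus centroid distance per ordered label
pair, and a `falls_within` flag that is true when every focal point lies
inside the reference hull (with a 1e-9 boundary tolerance). IoU was
chosen as the overlap fraction because it is symmetric and has the
expected endpoints (identical sets → 1, disjoint sets → 0). Hulls are
undefined below 3 points and reported as such.

## Synthetic generators (`synthetic`)

All generators are pure functions of their spec plus a seed, and every
ground-truth quantity they report is a closed form, never measured from
the generated object.

*Shapes.* The template is a closed 3D rim with five-fold radial and
vertical modulation — five peaks standing in for dentine horns on an EDJ
marginal outline — carrying five curves of (24, 23, 23, 23, 23)
semilandmarks, 116 in total; the per-curve split is a free choice
recorded here. Specimens are template + group deformation + allometric
term + isotropic Gaussian landmark noise, then randomly rotated,
translated and scaled. Deformation and allometry directions are
orthogonalized against the translation/rotation/scale tangent space at
the template, so injected effects are pure shape signals that survive
superimposition. Defaults: landmark noise SD 0.05 mm, group effect
magnitude 0.5 mm (10× the noise — a strong-separation regime), 20
specimens per group, lognormal size scatter 5%. What this does not
emulate: correlated landmark noise, measurement error structured along
curves, unbalanced groups, or real biological covariance — so passing
classification tests demonstrate correctness of the machinery under its
own assumptions, not expected accuracy on real teeth.

*Tooth phantoms.* Constructive solid geometry with closed-form volumes:
branch cylinders, a stem cylinder with an axial pulp cylinder, and
optionally a hemispherical dentine crown capped by enamel. A feature
thinner than 3 voxels raises an error stating the voxel size required.
The phantoms exist to validate the voxel metrics against analytic
truth (volumes within 2%, LAET within 5% at voxel ≤ radius/50); they do
not attempt realistic root curvature, cervical constriction or enamel
thickness gradients.

*Lithics.* Lognormal draws (mean-parameterized, so the expected value of
every column equals the class mean) with a common coefficient of
variation, default 0.15 — a plausible within-class spread for calliper
measurements on curated points and cores.

*Comparative samples.* Normal draws summarised by mean, sample SD (n−1)
and n, recomputed from the draws.

## Pipeline and reproducibility

`run_attribution` executes any subset of the four stages from a validated
config and writes a single JSON report (sorted keys, no timestamps), so
identical config + inputs give a byte-identical report; a failing stage
is recorded as failed without discarding completed stages. Seeds are
explicit arguments everywhere randomness exists; the package default is
20210215.

Problem sizes used by the shipped test and acceptance suites: 100,000
Monte-Carlo replicates per sample size for the coverage experiment;
shape samples of 20 specimens per group with 116 3D semilandmarks (348
variables); phantoms at 0.05 mm voxels (grids of roughly 10⁷ voxels);
lithic tables of 60–200 rows. These sizes keep every statistical
tolerance comfortably resolved while the full suite runs in seconds.

## I/O conventions and limitations

TPS support covers the LM3/LM, IMAGE and ID keys (unknown keys warn and
are ignored); curve structure travels in the long-format CSV dialect,
since TPS has no standard curve field. NRRD reading/writing is a minimal
in-house NRRD0004 subset (raw and gzip encodings, `spacings`/`space
directions` for voxel size); TIFF stacks go through tifffile and require
an explicit voxel size. Anisotropic voxel headers are rejected unless
overridden, because every tissue formula assumes physical isotropic
units. Meshes, DICOM and registration are out of scope.

Known limitations: automatic bifurcation detection requires a
near-axis-aligned cervical plane; the face-count area estimator is
orientation-biased (see above); no semilandmark sliding; posteriors
assume equal priors and a shared within-group covariance; and the
package deliberately reports both posterior variants rather than
deciding which one a given legacy toolchain printed.
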