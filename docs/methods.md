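# Methods

## Model and scope

The package computes a regional weakness score for the infrarenal aortic
wall from three image-derived inputs: the segmented lumen and outer-wall
surfaces, tracked outer-wall nodal positions over one cardiac cycle, and a
per-face wall-shear-stress (WSS) vector series. Upstream steps that
produce those inputs — segmentation, optical-flow feature tracking, and
the CFD solve — are out of scope; the pipeline consumes their outputs.
Microarray/ontology analysis of resected tissue is likewise out of scope.

The scoring model assumes: (i) the wall segment is a single non-branching
tube (iliacs excluded); (ii) node correspondence across phases, so strain
can be evaluated per triangle from vertex motion; (iii) the WSS series is
sampled on the wall faces and spans one cycle.

## Parcellation

The lumen centerline is extracted by cross-section centroid marching: a
first pass slices perpendicular to the principal (PCA) axis of the lumen
node cloud at `n_samples` stations inset half a step from the ends; two
refinement passes re-slice perpendicular to the current local tangent at
arclength-uniform stations, which removes the oblique-cut bias on curved
vessels. Plane/mesh crossings are computed edge-wise (robust when a plane
coincides with a mesh ring); when a perpendicular plane cuts the tube a
second time far away, the loop nearest the station is kept, and stations
whose cross-section does not wrap fully around (largest angular gap above
60°) are dropped — these arise where a plane exits an open end, so the
centerline may end slightly inside the rims. A section splitting into
multiple loops in the first pass is treated as branching and rejected.

Faces map to their nearest point on a densely resampled centerline; the
arclength there selects one of `n_axial` (default 6) equal-arclength bins,
and the sign of the centroid offset along the patient left and anterior
axes selects the quadrant, giving 24 patches by default. Whether the
original protocol binned by arclength or by a body axis is not decidable
from its description; equal arclength is the default and `n_axial`, the
axes convention (default DICOM LPS: left = +x, posterior = +y) and the
quadrant tie rule (offsets exactly on a boundary go to left/anterior) are
configurable/documented. Patch means are area-weighted (the alternative —
simple node means — is not offered); missing face values are excluded from
numerator and weight rather than imputed.

## Descriptors

**ILT thickness** is evaluated per outer-wall node against the lumen node
set inside a search radius (default 5 mm, a deliberate sensitivity knob of
the same order as typical regional ILT; every run logs it). Three
estimators are provided. The default, `nearest`, takes the distance to the
closest lumen node inside the radius and recovers the wall-to-lumen gap up
to lumen mesh spacing. `mean` averages the distances to *all* lumen nodes
inside the radius; because those distances range from the gap up to the
radius, it over-reads thin ILT by up to ~radius/2 and is only meaningful
with a radius close to the expected thickness — it is kept as the literal
reading of "average distance to neighbor points within a radius".
`surface` is point-to-triangle. Nodes with an empty neighborhood are
missing (NaN), not zero, and excluded from patch averages.

**TAWSS** integrates the WSS magnitude per face by the trapezoidal rule
with periodic closure (last phase wraps to the first); the period defaults
to the sampled span plus one mean spacing, so uniform sampling reduces to
the arithmetic mean. 

**Strain** builds, per face and phase, the 2×2 in-plane deformation
gradient mapping the reference triangle's edge vectors (in a local
orthonormal frame) to the deformed ones, then
`E = (FᵀF − I)/2`; the reported per-face value is the largest eigenvalue
of `E` maximised over the cycle (max-then-average ordering; whether the
original analysis took the peak over the cycle or the systolic phase is
not stated, so the reference phase and ordering are configurable).
Triangles below an area tolerance of 1e-12 mm² raise.

## Scoring

Quartile boundaries use linear-interpolation quantiles; category k covers
the k-th quartile interval with the lower boundary inclusive. Degenerate
reference sets (fewer than 4 finite values, or zero spread) give category
1 everywhere with a warning. The combined category is the arithmetic mean
of the patient-specific and population ranks — the one simple rule that
yields the half-integer categories seen in practice; the population pool
is whatever sample the categorizer is fitted on, so it is configurable.
RAW is reported rounded half-up to 2 decimals and stored at full
precision; classification at the default threshold 6 is strict (`> 6`).

## Ex vivo curve analysis

UTS is the stress at the first discontinuity — operationalized as the
first sample falling at least `drop_fraction` (default 2%) below the
running maximum, with failure placed at the preceding peak — or at the
global maximum when no such drop occurs. The 2% default absorbs load-cell
jitter; it is configurable. Strength class is strict (`< 0.3` MPa = low).
Energy loss is `100·(A_load − A_unload)/A_load` with trapezoidal areas on
the common abscissa interval, invariant to strain-vs-stretch abscissa,
clipped to [0, 100] with a warning if unloading exceeds loading.
Preconditioning cycles are expected to be trimmed upstream via branch
labels in the CSV, not auto-detected. Hysteresis uses hook-to-hook
(global) stretch curves; a marker-based local variant is not implemented.

## Statistics

Two-group comparisons gate on Shapiro–Wilk at α = 0.05 per group: both
normal → unpaired two-tailed t-test; otherwise, if all values are positive
and a log transform restores normality in both groups, the t-test runs on
the transformed data (summaries stay on the original scale); else
Mann–Whitney U. The same gate selects ANOVA vs Kruskal–Wallis for more
groups and Pearson vs Spearman for correlation. AUC uses the rank
(Mann–Whitney) identity with ties counted ½; its CI is a stratified
percentile bootstrap (default 2,000 replicates, seeded) — chosen over
DeLong for transparency, and stratified so every replicate keeps both
classes. No multiple-testing correction is applied, matching the original
analysis. Caveat: patch-level observations from the same patient are
treated as independent, as in the source protocol; within-patient
clustering is ignored.

## Synthetic data

The generator builds what the pipeline would otherwise receive from
imaging, with exact oracles:

* Wall and lumen are structured open tubes (49 rings × 48 nodes by
  default) sharing connectivity; the wall radius is fusiform
  (`sin²` bulge) from an 11 mm neck to a 27 mm maximum over 110 mm,
  matching a ~54 mm-diameter AAA. The lumen sits inward by a prescribed
  gap `g(z, θ)` (default: sac-concentrated, anteriorly biased, 8 mm peak,
  surface mean ≈ 2.7 mm). Tubes are open-ended (no caps): no downstream
  operation needs closure, and open rims keep the per-ring strain truth
  and centerline slicing exact.
* Motion is a uniform radial scaling `r → λ(t)·r`,
  `λ(t) = 1 + pulsatility·s(t)` with a raised-cosine `s(t)` over a 1 s
  cycle (20 phases). Because radial scaling stretches circumferential
  chords by exactly λ and every other in-surface chord by at most λ, the
  per-face peak principal Green–Lagrange strain is exactly
  `(λ_max² − 1)/2` — an analytic truth with no numerical oracle needed.
  The default pulsatility 0.0296 puts that peak at 0.03, a typical
  population mean. The raised cosine is a convenient surrogate, not a
  measured inflow waveform.
* WSS magnitude is `wss_peak·(r_neck/r_local)³` directed axially — the
  cubic radius dependence of Poiseuille wall shear at fixed flow — times a
  raised-cosine waveform with a 25% diastolic floor. With the 1.5 Pa neck
  default, sac TAWSS lands near 0.1 Pa and neck TAWSS near 0.6 Pa,
  bracketing typical patient means. This emulates the low-shear sac
  observation; it is not CFD.
* Tensile curves follow `σ = a(e^{bε} − 1)` up to a planted failure
  stress; `peak` mode rounds off after the maximum, `discontinuity` mode
  plants a sharp 10% tear followed by re-stiffening past the old maximum
  (so first-tear detection is exercised against a later global maximum).
  The unloading branch is a power law through the loop tips whose exponent
  is solved (Brent) so the trapezoidal hysteresis ratio on the emitted
  grid equals the planted fraction exactly; noise, when requested, is
  additive Gaussian on stress only. Geometry is noise-free by default
  (optional node jitter) so geometric oracles stay exact.
* `make_cohort` assembles a resected-cohort stand-in: nine patients with
  anatomy drawn around the defaults, each run through the full pipeline,
  and per-patch planted UTS that is log-normal with median decaying in the
  patch's normalised weakness (thick ILT, low TAWSS, high strain) —
  delivered as full curves and read back through the curve analyser, so
  weak regions carry genuinely lower measured strength with realistic
  group overlap.

What passing on these synthetics does *not* show: performance under
segmentation noise, real (non-affine) wall kinematics, true CFD shear
fields, branching anatomy, or registration error between patients. The
synthetic separation between RAW and planted strength is by construction
stronger than clinical reality; it validates the machinery, not the
clinical effect size.

All generation is a pure function of its config, including the seed.

## Numerical choices and limitations

* Quantiles: linear interpolation; category ties at a boundary take the
  lower category.
* Rounding for reported RAW: half-up, 2 decimals.
* Patch-boundary assignments depend on floating-point sign decisions;
  faces whose centroid lies exactly on a boundary are deterministic but
  not invariant to round-off introduced by rigid motion.
* Degenerate faces (area ≤ 1e-12 mm²) are rejected at mesh construction.
* Pipeline problem size defaults (49×48 rings, 20 phases, 60 centerline
  stations) resolve the default geometry well while keeping a full run
  under a second; they are configurable.
* VTK output is legacy-ASCII POLYDATA written by a purpose-built minimal
  writer (scalars and 3-vectors on points and cells), readable by
  ParaView/VTK; the matching reader supports only files of that dialect.
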