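# Methods

This note documents the measurement definitions, the synthetic-data model
behind the test suite, the numerical choices, and the known limitations of
`scquant`. Distances are nanometers throughout; densities per µm / µm².

## Coordinate model and calibration

A model is a set of annotated 3D points: two lateral-element (LE) regions,
one central-element (CE) region, and a list of transverse-filament (TF)
polylines. Point files use the 5-column `object contour x y z` dialect of
IMOD's `model2point -object`; coordinates are treated as continuous model
coordinates (no voxel-index convention). Pixel-space models are converted
to nanometers by multiplying x and y by the pixel size (default 0.287 nm)
and z additionally by a z-scale factor

    z_factor = nominal section thickness / (z extent × pixel size),

which compensates the thinning of plastic sections during data collection
(z_factor = 1 when no thinning occurred). Scaling is exactly invertible.

Element regions come in two representations. Real segmentations are *point
clouds*: membership is `distance-to-cloud ≤ δ` with a single tunable radius
δ (default 4 nm), making the boundary the δ-offset surface of the cloud —
robust to segmentation sparsity. Synthetic models additionally carry exact
*slab* (oriented-box) boundaries so tests can demand exact recovery.

## Per-filament measurements

Each filament is assigned to the LE nearest one of its endpoints. Endpoint
typing uses all three elements: an endpoint is an LE-end only if its
nearest element is a lateral element. (A two-LE comparison alone is
ambiguous — the CE-end of a well-formed filament is also nearer its
own-side LE than the opposite one.) Filaments whose endpoints resolve to
the same LE, or to no LE, are labeled unresolved, excluded from
side-specific statistics, and reported.

Walking the polyline from the LE-end gives the intersection with the
own-side LE boundary; walking from the CE-end gives the CE intersection.
The crossing on the straddling segment is located by bisection on the
membership predicate. Segment lengths are Euclidean distances between the
relevant endpoint/intersection pairs; the total length is the distance
between the two endpoints. A filament missing an intersection keeps `nan`
in the affected fields and is excluded from the affected summary only;
exclusion counts are logged.

Widths are nearest-neighbor distances between point sets: CR width (each
LE intersection vs the opposing LE's intersections, both sides
contributing), LE–CE (LE intersections vs same-side CE intersections), CE
width (CE intersections across sides). These estimators are positively
biased relative to the wall-to-wall geometry — the nearest opposing sample
point is almost never exactly opposite — and the bias grows with sparse or
depth-scattered insertion points. This is a property of the measurement
definition, not an implementation artifact; it is why the three published
width means are not mutually additive.

CE nearest-neighbor spacings use CE *endpoints*: the minimum distance to a
same-side endpoint (parallel) and to an opposite-side endpoint (opposite);
LE spacing is the same within one LE. Pairing classification is a
threshold rule: opposite if the opposite-NN is ≤ 15 nm, else parallel if
the parallel-NN is ≤ 15 nm, else single. The threshold sits below both
published NN means so only markedly close neighbors count as pairs;
opposite takes precedence. Asymmetry is `100·|n_L − n_R| / max(n_L, n_R)`,
the denominator chosen so that 100 vs 79 filaments reads as exactly 21%.

Densities project the insertion points (CE intersections by default, or
one side's LE endpoints) onto their best-fit plane and fit an axis-aligned
rectangle to the per-axis extrema of the projected coordinates: TFs/µm =
total filament count / rectangle length; TFs/µm² = site points / rectangle
area.

Cohort summaries concatenate the underlying per-filament and per-point
samples (all tomograms as one data set) rather than averaging per-tomogram
means; densities and asymmetry are summarized across tomograms. All "±"
values are sample standard deviations (n − 1), appropriate for the small
per-tomogram sample sizes.

## Rank-sum test

Two-sided Wilcoxon rank-sum. For tie-free samples with n₁+n₂ ≤ 16 the
exact null distribution of the rank sum is computed by dynamic programming
over rank subsets (p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1); otherwise a
normal approximation with midranks, tie-corrected variance and a 0.5
continuity correction is used. The exact path is verified against full
enumeration and against an independent implementation in the test suite.

## Layer analysis

The bilayer hypothesis predicts two parallel planes of filaments at a
designated spacing. Per side, both endpoints of each filament enter a
k-planes (k = 2) fit: points are assigned to the nearer plane by orthogonal
distance and each plane is refit by orthogonal regression (normal = the
smallest-eigenvalue eigenvector of the centered second-moment matrix),
iterating to convergence. Initialization uses the sign of the single-plane
residual (the fixed point for planted parallel bilayers) plus 10 random
balanced partitions to escape local optima such as the longitudinal split
of a curved sheet; the lowest-SSE converged candidate wins, and two-plane
SSE never exceeds the single-plane SSE by construction. Using both
endpoints makes a filament layer a *filament-axis plane*; CE endpoints
alone leave the fit dominated by the small embedding-depth spread and
remain available as a sensitivity option.

The bilayer verdict requires four criteria, all exposed in `LayerConfig`:

1. plane normals within 20° of parallel;
2. spacing ≥ 4× the pooled within-cluster rms *and* ≥ 5 nm. A two-plane
   split of unimodal noise already produces spacing ≈ 2.7× rms (Gaussian;
   3.5× for uniform) because the split itself separates the halves, so a
   2–3× threshold would label any noisy monolayer a bilayer; the absolute
   floor guards the exactly coplanar case (0 ≥ k·0);
3. longitudinal coexistence: ≥ 50% of occupied bins along the SC long axis
   contain points of both clusters. Interval overlap is not enough — a
   curved monolayer spanning several bend periods produces clusters that
   alternate along the length while their [min, max] intervals coincide;
4. the stacking direction (mean plane normal) at least 60° away from the SC
   width axis. Layers contain whole filaments spanning LE→CE, so a layer
   plane must contain the width axis; this rejects the two parallel sheets
   (LE endpoints vs CE endpoints, ~60 nm apart along the width axis) that
   every SC possesses regardless of layering.

Verdicts are monolayer when a converged fit fails any criterion, and
inconclusive on degenerate fits or fewer than 8 points. The 2D
lateral-view projection of the CE intersection points uses the plane
normal to the width axis; a free plane fit is the fallback when no width
axis is available (for a thin monolayer the free fit flips its normal onto
the depth axis, because the CE point sheet is thinner in depth than its
29 nm cross-width).

## Synthetic SC generator

The generator plants a straight (optionally sinusoidally curved) SC along
x, width along y, depth along z. Defaults reproduce the measured cohort:
CR width 114 ± 17, CE width 29, LE thickness 40, TF totals 88 ± 14 with
indents 21 ± 9 (LE) and 14 ± 7 (CE), 79 TFs/µm counted over both sides.
Because the implied midsection mean (53 nm) exceeds the flat LE→CE gap
((114 − 29)/2 = 42.5 nm), filaments are oblique: the midsection chord spans
the gap at angle arccos(gap/midsection). The tilt direction is mostly
longitudinal with a Gaussian azimuth spread (default sd 35°), which sets
the depth scatter of the endpoints and hence the areal density; 35° puts
the implied TFs/µm² near the published order and keeps the density
projection in the lateral view.

Filaments are straight 5-point polylines (lengths are endpoint distances,
so curvature would add untestable freedom). Anchors on a jittered grid
host the planted pairing classes (default mixture parallel : opposite :
single = 0.25 : 0.5 : 0.25; the published record gives no proportions):
an opposite pair is two mirror-twin filaments, one per side, whose CE
endpoints share a locus within 5 nm in the CE plane; a parallel pair sits
on one side with the same offset bound; singles occupy their anchor alone.
Per-side counts come from a Poisson draw of the total and the asymmetry
fraction (difference relative to the larger side). In bilayer mode anchors
are offset ±gap/2 in depth; the SC course adds a sinusoidal depth shear.

Length draws are made one per *filament* with symmetric two-sided
truncation about the configured mean (floor 1 nm; midsections floored at
the realized gap), so configured means are preserved exactly in
expectation — a one-sided floor would bias them. A pair's shared value is
the average of the two draws its members consume, which keeps the
per-filament mean at the pool mean regardless of routing; opposite pairs
consume the deepest CE-indent draws so that head-to-head pairs embed
deeply enough to be recoverable by the 15 nm classifier (the cross-CE
depth gap 29 − 2·c·cosθ would otherwise exceed the threshold for shallow
indents). Element point clouds are sampled on the element volume eroded by
`cloud_margin_nm` (default 4 nm = the default membership δ), so the
δ-offset membership surface coincides with the true boundary.

`GroundTruth` records every per-filament truth *before* endpoint jitter,
plus realized aggregates: for each estimator, the value of the same
functional evaluated on the noise-free geometry. Recovery tests compare
the measured estimate against that realized value — the honest target,
since the NN-width functionals carry irreducible geometric inflation that
no estimator could remove.

### What the generator does and does not emulate

It emulates the measured geometry, pairing structure, asymmetry, layering
and section curvature. It does not emulate: curved filament traces,
segmentation errors other than isotropic Gaussian endpoint jitter
(default sd 2 nm), missing or truncated filaments at section boundaries,
intensity-based measures (TF diameter is an image measurement, carried
only as a ground-truth attribute), chromatin, or nuclear-envelope
attachment. Passing tests therefore demonstrate correctness of the
measurement pipeline under known geometry and noise — not robustness to
every failure mode of manual segmentation.

Planted layer conditions set the tilt azimuth spread to zero: a "bilayer
with 30 nm gap and 3 nm jitter" means layer-coherent filaments; filaments
tilted ±35° out of plane scatter endpoints ±30 nm in depth and do not form
planes at all.

## Numerical choices

- Boundary-crossing bisection tolerance: 1e-8 nm (so zero-noise recovery
  is exact to ≤ 1e-6 nm; far below the 0.287 nm pixel either way).
- Plane normals carry a fixed sign convention (non-negative z, ties broken
  by y then x), making serialized results identical across runs; the same
  convention orients projection axes.
- Exactly coplanar two-plane fits are kept stable by letting equidistant
  points keep their current cluster during alternation.
- Degenerate inputs degrade to reported `nan`s or `inconclusive` verdicts,
  never silent exceptions; exclusions are logged at INFO.
- Per-tomogram seeds in a cohort are master seed + index (mod 2³¹).

## Problem sizes in the shipped tests

The test suite and the acceptance script use: one ~2 µm zero-noise model
(~160 filaments); a six-tomogram cohort of ~1 µm each (~500 filaments);
one ~26 µm model (~2000 filaments) for the law-of-large-numbers check; and
20 seeds per planted layer condition at ~100 filaments per side. These
sizes keep the full suite under a minute on one CPU while leaving sampling
error well inside the asserted tolerances.

## Known limitations

- The width estimators inflate with sparse insertion points; compare like
  with like (the realized ground-truth functional), not the wall-to-wall
  geometry.
- The pairing classifier is a hard threshold; filaments near 15 nm
  spacing flip class under jitter, which bounds planted-class recovery at
  ~90–95% under the default 2 nm jitter.
- The layer verdict tests the two-layer hypothesis only; three or more
  layers (as in some insects) are out of scope.
- A flat monolayer whose depth scatter is genuinely bimodal cannot be
  distinguished from a tight bilayer by any of the four criteria; the
  verdict is only as meaningful as the planted contrast.
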