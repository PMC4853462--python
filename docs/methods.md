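# Methods

This note documents the models, algorithms and numerical choices
behind `cartbox`, and what its synthetic validation does and does not
demonstrate.

## Problem setting

Catheter-based electromechanical mapping (EMM) measures unipolar (UV)
and bipolar (BV) depolarization voltages and linear local shortening
(LLS) at scattered points on the left-ventricular endocardium, in the
mapping system's own coordinate frame.  Late-gadolinium-enhancement
MRI provides the reference infarct geometry as segmented short-axis
contours.  The package fuses the two: it builds an endocardial surface
mesh from the contours, rigidly registers the EMM point cloud onto it,
maps infarct transmurality (IT, the percent of the wall cross-section
occupied by scar) into 80 circumferential segments per slice, and
quantifies how well each EMM parameter identifies tissue of a given
transmurality (ROC threshold sweeps) and how much IT variance it
explains across animals (random-intercept mixed models).

Coordinates are a right-handed patient-like frame (x left, y
posterior, z toward the head), all lengths in mm.  Slices are ordered
base→apex (strictly decreasing z).  Circumferential segment 0 starts
at the +x axis and indices increase counterclockwise as seen from the
apex; the convention is declared, since no standard fixes the origin
of an 80-segment ring.

## Endocardial mesh

Each slice's end-diastolic endocardial polygon is resampled to 80
equal-arclength points (orientation normalized counterclockwise viewed
from the base).  Adjacent rings are angularly aligned by a discrete
cyclic-shift search minimizing summed inter-ring vertex distance,
which prevents twisted stitching; rings are joined with 160 triangles
each and the apex is closed by a fan to the centroid of the most
apical ring, which becomes the apex vertex — the pivot of every
registration rotation.  No smoothing or decimation is applied.

Closest-point queries are exact: per query the candidate triangles are
the k nearest by centroid (plus all oversized triangles, e.g. the apex
fan), with a provable sufficiency bound — if the k-th centroid is
farther than the best distance found plus the largest remaining
triangle radius, no unseen triangle can win; violators are rescanned.
Containment uses the generalized winding number of the basally capped
surface, so everything on the atrial side of the base (LV outflow
tract) is outside by construction.  Scattered fields (IT, wall
thickening) are projected onto mesh vertices by piecewise-linear
interpolation (Delaunay-based), with nearest-sample fallback outside
the convex hull; values are therefore range-bounded by the samples.

## Registration chain

1. **Standard axes.**  A constant named rotation maps the mapping
   system's frame onto the MRI frame (configured per site; identity
   when both datasets share the package frame).
2. **Apex and long-axis alignment.**  The EMM long axis is estimated
   by refining each principal direction of the cloud with band-wise
   circle-centre fits (Kåsa) and keeping the candidate whose
   cross-sections are most circular; circle centres are insensitive to
   the strongly inhomogeneous angular point density of mapping
   acquisitions, which badly biases raw PCA.  The apex end is the
   closed (small-radius) end; the apex estimate is the most extreme
   point along the axis, tie-broken toward the axis.  The cloud is
   translated apex→apex and tilted axis→axis.  Because the apex
   estimate is a sampled point (good only to the local point spacing,
   ~5–10 mm at 150 points), the translation is polished by iterating
   the mean offset to the closest-surface feet; the residual rotation
   about the long axis is then resolved by a 1-D search minimizing the
   mean point-to-surface distance.
3. **Rotation-constrained ICP.**  Iterate: match every included point
   to its closest surface foot point; solve the least-squares rigid
   update by SVD (Kabsch); clamp the *cumulative* Euler angles about
   the apex to ±(10, 20, 20)° in the sagittal/coronal/transverse
   planes (the bound is on total rotation, to prevent excess
   rotations, so clamping projects the cumulative angles onto the
   box).  Stop when the mean-distance improvement falls below 0.01 mm
   (well below the millimetre error scale of interest) or after 100
   iterations; updates that would increase the mean error are
   rejected, so the accepted trace is non-increasing.
4. **Roll re-search and bounded fine optimization.**  Point-to-foot
   ICP has a structural blind spot on near-rotationally-symmetric
   surfaces: its update has no first-order component along
   surface-tangential motions, so rotation about the long axis (and
   the coupled tilt-plus-translation "rocking" mode of a cup-shaped
   surface) is essentially never corrected — we measured residuals of
   3–12° even on noise-free data.  The chain therefore finishes with a
   second ±20° roll search and a derivative-free (Powell) minimization
   of the mean closest distance over all six degrees of freedom, with
   each rotation bounded to 5° — the same cap enforced for manual
   tweaks, making this stage the automated counterpart of the
   interactive fine adjustment of the original workflow.
   `manual_adjust` remains available as the programmatic bounded
   6-DOF API and refuses any single rotation above 5°.

Points outside the capped cavity and farther than 5 mm from the
surface are excluded after initial alignment and before ICP; analyses
additionally exclude points whose closest vertex lies in the two most
basal slices (count configurable — the valvular plane carries
collagen-rich low-voltage tissue without LGE contrast).  The
registration error is the mean ± SD (sample SD, n−1) of the closest
point-to-surface distance over included points.

## Transmurality, wall thickening, border zone

IT is *area based*: the myocardium (epi minus endo) and scar∩myocardium
are rasterized at the stack's pixel spacing (default 0.25 mm), pixels
are assigned to 80 angular sectors about the ED endocardial centroid,
and IT per sector is 100·scar/wall pixel counts; sectors without wall
pixels are missing.  The five IT classes partition [0, 100] with
upper-inclusive boundaries and {0} its own class.  Wall thickening is
the ES-minus-ED radial wall thickness per sector, measured along rays
from the same centroid (3 rays per sector averaged); it may be
negative over transmural scar.  The border zone is declared as the
infarcted non-transmural rim (0 < IT ≤ 75 by default, overridable),
optionally restricted to vertices edge-adjacent to the transmural
core; the original automatic algorithm is unpublished, so this is a
minimal stated definition, not a reproduction.

## LLS and point densities

LLS of a point is the weighted mean percent decrease of its distances
to all other points from end diastole to maximal systole, normalized
by the ED distances.  The neighbor weighting emphasizes separations of
8–15 mm (tent window ramping from 4 and 25 mm); the exact proprietary
kernel is unpublished, so the window sits behind a single function and
every asserted property (uniform scaling by s gives exactly
100(1−s) %, rigid-motion invariance) is weight-independent.  Point
densities per IT class divide the included point count whose closest
vertex falls in a class by the summed endocardial segment area of that
class (triangle areas accumulated into slice×segment bullseye cells).

## ROC grids and mixed-model R²

The ROC layer sweeps 40 reference cutoffs against 40 predictor
thresholds.  Cutoffs are min + k·step (k = 0…39), thresholds
min + k·step (k = 1…40); with the shipped ranges (IT 0–100 % step
2.5; UV 0–25 mV step 0.625; BV 0–12 mV step 0.3; LLS −32–48 % step 2;
WT −5–15 mm step 0.5) every clinically quoted value (IT ≥5 %, ≥97.5 %;
UV ≤9.375 mV) lies on the grid.  Disease-positive is reference ≥
cutoff; test-positive is predictor ≤ threshold (low voltage = scar;
direction configurable).  Per cutoff, AUC is the trapezoid area of the
empirical (1−specificity, sensitivity) curve with (0,0) and (1,1)
anchors; cutoffs with an empty class are missing.  The operating point
maximizes Youden's J, ties resolved to the lower threshold
(conservative for ≤-positivity).  Note a selection effect inherent in
"best cutoff by AUC": under a null (independent) predictor the maximum
over 40 cutoffs sits near 0.55, not 0.50, because extreme cutoffs have
tiny classes and noisy AUCs; chance-level checks should read
well-populated cutoffs.

Variance explained by an EMM parameter uses two Gaussian
random-intercept models fitted by maximum likelihood (ML, not REML, so
the null and full criteria are comparable): R² = 1 − (σ²_full +
τ00_full)/(σ²_null + τ00_null), where σ² is the within-animal residual
variance and τ00 the between-animal intercept variance.  A zero-variance
covariate degenerates the full model to the null (R² = 0); a boundary
fit (τ00 → 0) is flagged, not an error.

## Synthetic phantom

The phantom defines the study conditions.  The endocardium is an
ellipsoid with semi-axes (25, 25, 60) mm truncated at the base
(default at the equator; `base_truncation_fraction` raises the base
above it), wall 10 mm, 20 slices, emulating the roughly 20-slice
apex-to-base segmentations of a porcine LV.  The infarct is a smooth
IT field — peak 95 %, raised-cosine falloff over a 120° angular width
and 0.6 of the apex-base extent — realized per slice as a scar contour
whose in-plane radial extent reproduces the local area fraction, so
the rasterized measurement has an analytic reference.  ES contours
thicken the wall by 6·(1 − IT/100) mm (healthy myocardium thickens,
scar does not), so the generative coupling is recoverable from the WT
bullseye by regression.

EMM sampling draws 150 points (a typical porcine mapping
acquisition) per-triangle-area weighted, with a 2× boost where IT > 75 %
(catheters dwell in and around the infarct), jittered by isotropic
Gaussian contact noise (default σ = 1 mm).  Voltages follow a linear
IT link (UV 12→4 mV, BV 3→0.5 mV healthy→scar, Gaussian noise 1.5 /
0.4 mV): these bracket the clinically used 9.38 mV / 1.2 mV cutoffs so
threshold-recovery simulations land mid-grid; they are simulation
knobs, not physiological claims.  LLS comes from the package's own
definition applied to simulated ED/ES trajectories (radial contraction
15 % in healthy tissue, scar akinetic).  Everything is deterministic
given (spec, seed).

**Registration study conditions.**  Recovery experiments use semi-axes
(25, 30, 60) mm, base above the equator
(`base_truncation_fraction = 0.3`) and contact noise σ = 0.3 mm: on a
perfect surface of revolution rotation about the long axis is
mathematically unidentifiable, and a half-ellipsoid cup can rock with
almost no misfit, so a mild cross-sectional ellipticity and an
above-equator base — both features of real ventricles — are required
for the 6-DOF recovery to be well-posed; σ = 0.3 mm reflects
sub-millimetre magnetic tracking.  Under these conditions the full
chain recovers perturbations within (±8, ±15, ±15)° / ±10 mm to better
than 2° per axis and 1 mm (worst case over 20 seeds), with the final
mean error at the noise floor (≈0.8σ, the mean absolute normal
component of isotropic jitter).  At σ = 1 mm with 150 points the
tilt/roll directions of the objective become flat enough that
worst-case recovery degrades to ~3–5°: an identifiability limit of the
geometry, not an implementation artifact.

**What the phantom does not emulate:** papillary muscles and
trabeculation, true LVOT geometry, respiratory and heart-rate-induced
shape change between acquisitions (the dominant real-world error
source behind the ~3 mm in-vivo registration error), EDV mismatch
between EMM and MRI sessions, far-field voltage physics, and
segmentation error in the contours.  Passing phantom tests shows the
chain recovers known rigid misalignments under its stated noise model;
it does not bound in-vivo accuracy.

## Numerical choices and limitations

- Closest-point queries and containment are exact; tests pin them to
  exhaustive scans (1e-9) and an independent ray-parity oracle.
- ICP tolerance 0.01 mm, max 100 iterations; roll searches 2.5°/0.4°
  (±20°) and 5°/0.8° (global); Powell polish with 5e-3 step tolerance
  and 250 evaluations — all far below the millimetre scale of
  interest.  Problem sizes throughout (20-slice phantoms, 150–400
  points, 10–20 Monte-Carlo seeds) were chosen so that every study
  runs in seconds to a couple of minutes on one core.
- File numerics use %.6g (sub-micrometre at these scales); bullseye
  round-trips are exact to ~5e-5 at IT ≈ 100 %.
- Degenerate inputs error loudly (typed exceptions): <3 slices,
  zero-area rings, self-intersecting polygons, endo outside epi,
  non-monotone z, duplicate point ids, empty included sets, <4
  projection samples, out-of-range IT.
- The mixed-model layer assumes Gaussian outcomes and a single random
  intercept; per-point IT in vivo is zero-inflated and bounded, so the
  R² should be read as the paper's variance-ratio statistic, not as a
  calibrated fraction for arbitrary data.
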