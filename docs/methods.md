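# Methods

`volstorm` processes volumetric scanning 3D-dSTORM acquisitions: repeated
axial scans of a thick tissue block are merged into one drift-corrected
point cloud, presynaptic protein clusters are segmented and quantified,
and clusters are assigned to membrane-labeled boutons.  This note
documents the models, parameter choices, numerical conventions and known
limitations.

## Coordinate and unit conventions

All distances are nanometres unless a field is explicitly documented in
micrometres (scan travel, volumes).  The origin is the field-of-view
corner, x right, y down, z away from the coverslip.  Frames are 0-based.
Lateral binning is half-open, `[k·b, (k+1)·b)`.  The intensity filter is
inclusive (`intensity >= threshold`), and the eight-localization cluster
cut-off admits clusters with exactly eight members.

## Astigmatic z calibration

A cylindrical lens makes the fitted PSF widths `wx` and `wy` asymmetric
functions of defocus.  Calibration sweeps a coverslip bead sample axially
at constant speed, averages the fitted widths in 10 nm stage bins, and
smooths `wx(z)` and `wy(z)` with cubic smoothing splines
(`scipy.interpolate.make_smoothing_spline`; the penalty defaults to
generalized cross-validation, which leaves a residual RMS near the width
noise).  The calibration is valid only on the interval where the
discriminant `d(z) = wx(z) − wy(z)` is strictly monotone and crosses
zero; the focal plane is the root of `d`.  A flat or non-crossing
discriminant raises a calibration error ("astigmatism not resolvable").

Lookup minimizes `(wx(z) − Wx)² + (wy(z) − Wy)²` by a 1 nm grid search
with parabolic refinement, rather than inverting `d`: the two-curve
distance stays well-behaved when only one width is noisy.  Lookups whose
width-space residual exceeds 50 nm (default) are flagged rejected and
dropped during assembly, with an exact tally.  The calibration sweep's z
axis is recorded on the emitter-defocus axis (positive = above the focal
plane), so that assembled `z = stage_z + lookup offset`; a sweep recorded
with the opposite stage convention must be sign-flipped on import.

The synthetic defocus model `w(z) = w0·sqrt(1 + ((z ∓ c)/d)²)` with
`w0 = 150 nm`, `c = 400 nm`, `d = 500 nm` is a simulator convention only;
the spline calibration never assumes a functional form.

## Scan geometry and assembly

A `ScanSpec` describes the acquisition: by default ten 15,000-frame
movies at 100 Hz, the piezo travelling 10 µm per movie at constant speed
and inverting direction after each scan, so consecutive movies join
seamlessly.  The per-frame stage position uses a `(frames − 1)`
denominator so both endpoints are reached.  A localization is attributed
to its frame's stage position without motion-blur correction: at the
default speed the within-frame travel is ~0.67 nm, far below
localization precision.  Assembly concatenates the per-scan tables,
computes `z = stage_z(frame, scan) + astigmatic offset`, and preserves
exact count bookkeeping (kept + rejected = input).

## Drift correction and round alignment

Fiducial beads on the coverslip are imaged before and after each
measurement.  `summarize_beads` collapses bead localizations to one mean
position per bead (single-linkage merge within 100 nm; beads with fewer
than 10 localizations are discarded).  Pre/post sets are paired by
mutual nearest neighbour within 500 nm; a second matching pass after
subtracting the median displacement protects the least-squares
translation from a single crossed pairing when beads lie close together.
Optional in-plane rotation is solved by orthogonal Procrustes (SVD, with
a proper-rotation guard); a uniform scale can be added for round
alignment.  Drift is interpolated linearly in acquisition time between
the two bead epochs — with anchors only at the ends no richer model is
identifiable, and a non-linear component (e.g. an instantaneous jump at
mid-acquisition) leaves a predictable residual of half its amplitude at
the discontinuity.  Sequential staining rounds are mapped into the
reference frame with the same machinery; the residual is reported so
users can judge whether a rigid model is adequate.  Elastic warping is
deliberately out of scope: ~10 beads cannot constrain it.

## Density maps and cluster segmentation

Segmentation renders the point cloud into a localization-density map
(an open replacement for commercial isosurface modules), thresholds it
and takes 26-connected components.  Each localization deposits a
separable anisotropic Gaussian (defaults: σ = 30 nm lateral, 60 nm
axial, reflecting the poorer axial precision) on a 20 nm voxel grid.
Per-axis kernels are evaluated at voxel centers relative to the exact
localization position, truncated at 3σ and renormalized, so the map
integral times the voxel volume equals the deposited count.  Two code
paths give identical numbers: a dense array for small grids, and a
sparse path (only voxels inside kernel supports are materialized; the
above-threshold set is labeled via a sorted-key neighbour search and
`scipy.sparse.csgraph.connected_components`) that keeps the full
25 × 25 × 10 µm window — about 10⁹ voxels dense — within a ~2 GB
footprint on one CPU.

The density threshold defaults to five times a robust background
estimate (total count over the data bounding volume) and is recorded in
every output.  DBSCAN (eps 100 nm, minPts 8) is used for *denoising*
before segmentation; a pure-DBSCAN segmentation mode exists behind a
flag for sensitivity analysis.

Per cluster the package reports:

* `count` — member localizations (blinking events), the relative
  protein-content proxy;
* `length` — 3D Feret diameter of the members (max pairwise distance,
  accelerated over convex-hull vertices), rotation-invariant and
  reproducible where 2D studies used a freehand line;
* `mask_length` — Feret diameter of the segmented voxel mask, i.e. the
  reconstructed object's own extent;
* `width` — extent along the second principal axis of the members;
* `volume` — above-threshold voxel count × voxel volume (µm³);
* `density` — exactly `count / volume`.

Two length notions are deliberate.  The member Feret shrinks when fewer
events are recorded simply because extreme points are sampled less; the
mask length is the property that is stable under proportional threshold
scaling (see the reduction analysis) and is also what a single
localization's isosurface artifact (~0.16 µm at these rendering
parameters) refers to, so the minimum-length floor is applied to it.
A single localization's rendered size is determined entirely by
(kernel σ, threshold) and is not claimed to match any particular
commercial renderer.

## Truncation analysis

A cluster is flagged truncated when any member lies within a margin
(default one voxel) of a region-of-interest face along the checked axes
(z by default — axial truncation is the bias volumetric scanning is
designed to remove).  In thin sections the flag acts as a size-biased
filter: large clusters cannot avoid the borders, so the non-truncated
subset is enriched in small clusters and its median volume falls below
the unfiltered median.  The synthetic generator reproduces this regime
by making border-straddling size-determined — the axially largest
requested fraction of clusters straddle, tip-clipped with their center
inside the block — which is the thin-section limit of the selection
effect.

## Localization-reduction robustness

`subsample` implements the exact deterministic schemes: omitting every
10th/5th/3rd/2nd localization (90/80/66/50%) and keeping every
3rd/5th/10th (33/20/10%), 0-based, order-preserving.
`reduction_experiment` segments each thinned table with the density
threshold scaled by the same fraction and a 160 nm mask-length floor,
then tests the pooled mask-length distributions with Kruskal–Wallis.
Because the expected density scales linearly with the retained fraction,
the expected isosurface boundary — and hence the object extent — is
invariant; stability of the recovered median length down to 20% retained
is the designed outcome, and the omnibus test stays non-significant on
synthetic scenes.

## Bouton reconstruction and assignment

The membrane channel paints bouton surfaces, so its density map is
thresholded at a gentler level (1× the robust background estimate by
default — a surface's local density sits near the scene mean).  The
binary shell is morphologically closed (ball radius 3 voxels), filled,
and eroded back to the membrane midsurface using a self-calibrated
offset (the median Euclidean depth of the raw above-threshold band
inside the filled region estimates how far the outer isosurface sits
beyond the membrane midline).  Connected components above a minimum
volume (default 1 µm³) become boutons; optional seed points split
touching candidates by nearest-seed voxel assignment — the only
user-in-the-loop step, mirroring manual bouton/axon separation.
Volumes recover simulated shells of 2–28 µm³ within ~5%.

A cluster belongs to the bouton whose filled mask contains its centroid
voxel (boundary voxels inclusive); masks are disjoint, so assignment is
deterministic, and per-bouton tallies plus the Spearman correlation of
bouton volume against assigned cluster number are reported (omitted
below three boutons).

## Synthetic scenes and what they do and do not show

`SceneSpec` defaults define the validation conditions: a 25 × 25 µm
window scanned over 10 µm in ten alternating 15,000-frame movies;
200 prolate-ellipsoidal clusters (uniform interior fill, aspect 0.2,
lognormal lengths with median 450 nm); negative-binomial blinking
budgets with mean 139 and SD 80 events per cluster; 0.5 background
localizations per µm³; ten coverslip beads; localization precision
(15, 45) nm; 5 nm width noise; linear drift (30, −20, 15) nm; 5%
photobleaching per scan; ±500 nm astigmatic capture half-range.  An
emitter is visible only while the focal plane is within the capture
range of its position; blinking is i.i.d. Poisson per emitter per
in-focus pass (~0.5 events), with emitter numbers sized so the expected
budget matches the draw.  Ground truth records, per cluster, the
envelope geometry, the realized emitter Feret diameter and the emitted
event count; per-localization labels are kept for every movie.

Ground-truth conventions worth noting:

* *Length*: with finitely many emitters the ellipsoid's extreme poles
  carry essentially no probability mass, so the realizable length of a
  cluster is the Feret diameter of its emitter set (~0.7–0.8× the
  envelope axis), and recovery is scored against that, not the envelope.
* *Volume*: an isosurface volume depends on kernel and threshold, not
  only on the emitter envelope; the expected segmented volume of a true
  cluster is computed numerically (uniform-ellipsoid density scaled to
  the true count, convolved with the kernel broadened by the
  localization precision, thresholded) and recovery is scored against
  it.  This matches the semantics of isosurface-derived volumes in the
  source workflow.

The generator is deliberately not a photophysics model: no dark-state
kinetics, no camera-frame synthesis, no scattering, no spatially varying
PSF.  Passing tests therefore demonstrate that the pipeline's geometry,
bookkeeping and statistics are correct under controlled conditions; they
do not certify performance on tissue with structured background,
repeated blinking bursts of one fluorophore, or field-dependent
aberrations.

## Statistics

Distributions are summarized as median with 25th/75th percentiles
(type-7 linear interpolation; published quartiles under another
convention may differ in the last decimal), with mean ± SD available for
comparability.  Mann–Whitney U (exact for tie-free groups of ≤ 20,
normal approximation otherwise), Kruskal–Wallis (chi-square
approximation, tie-corrected) and Spearman rank correlation (average
ranks, t-approximation p) wrap `scipy.stats`.  Identical groups return
p = 1.  Significance stars follow *p < 0.05, **p < 0.01, ***p < 0.001.
The Mann–Whitney type-I error rate under a simulated null (n = 100 per
group, 1000 replicates) is verified to lie in [0.035, 0.065].

## Problem sizes used in validation

The end-to-end recovery scene keeps the full study geometry
(200 clusters in 25 × 25 × 10 µm, ten scans, ~30k localizations).  The
reduction analysis runs on a 15 × 15 × 1 µm single-section cloud with
150 clusters; the truncation analysis on 18 × 18 × 1 µm with 200
clusters and a broader length spread (lognormal σ 0.45) mirroring the
wide size distribution of thin-section data; drift and calibration
checks use smaller fields where the quantity under test does not depend
on scene size.  One published worked example — summary statistics of the
21 individually identified boutons — requires a per-bouton supplementary
table that is not distributed with the text available to this package
and is therefore not recomputed; the machinery it would exercise is
validated on synthetic data instead.

## Known limitations

* Rigid (plus optional similarity) round alignment only; residuals are
  reported so inadequacy is visible, but elastic deformation is not
  modeled.
* Drift is linear in time between two bead epochs; faster drift
  components alias into localization scatter.
* Bead z at the coverslip is extrapolated unchanged to imaging depth;
  there is no depth-dependent drift or aberration model.
* The isosurface surrogate is not a reimplementation of any commercial
  renderer; absolute volumes depend on (kernel σ, voxel, threshold) and
  are comparable within a parameter set, not across tools.
* Cluster assignment uses centroid-in-mask only; a cluster straddling a
  bouton surface is assigned entirely or not at all.
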