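# Methods

This note documents the models, parameter choices and numerical decisions
behind `pvsquant`, and what the phantom-based validation does and does not
establish.

## Vesselness filter

The tube enhancement is a multi-scale Hessian line filter. At each scale σ
(mm) the image is convolved with Gaussian second-derivative kernels (σ
divided by the per-axis voxel spacing, so the scales are physical); the
Hessian is scale-normalised by σ² (γ = 1 per derivative order) so responses
are comparable across scales, and the per-voxel output is the maximum over
10 uniformly spaced scales from 0.30 to 1.00 mm — matched to PVS radii of
0.15–0.70 mm. Eigenvalues are sorted by magnitude |λ1| ≤ |λ2| ≤ |λ3|; inside
a bright tube λ2, λ3 < 0 and λ1 ≈ 0, with the λ1-eigenvector along the tube
axis (this vector seeds the tracker). The single-scale response is the
classic bright-line form

    λc · (1 + λ1/|λ2|)          if λ1 ≤ 0
    λc · (1 − α λ1/|λ2|)        if 0 < λ1 < |λ2|/α,     λc = |λ3| (λ2/λ3)^γ23

with defaults α = 0.25, γ12 = γ23 = 1, all exposed in `VesselnessConfig`:
the exact shape exponents of historical implementations vary, so they are
explicit and overridable here rather than hidden. Boundary handling is
reflect padding; the constant image baseline is subtracted before filtering
because truncated derivative kernels do not sum exactly to zero, which makes
the response exactly invariant to adding a constant to the image. When a
region-of-interest mask is supplied, smoothing still uses the surrounding
image but the eigen-decomposition is restricted to the masked voxels.

## CSO plane and ROI

The plane normal is unit((genu − splenium) × midsagittal-normal), oriented
to a positive superior component; the plane point is the ventricle-top
landmark offset 10 mm along the normal. "7 slices" is read on the
reconstructed grid: the slab spans ± (7 × grid step along the normal)/2,
centred on the plane (a one-sided reading is possible; centring is the
package's choice and both the slice count and spacing are configurable).
Landmarks are inputs — automatic corpus-callosum or ventricle detection is
a separate problem and out of scope.

## kNN classification

Features are the T1 intensity, T2 intensity and vesselness value, each
z-scored over the subject's white matter. Standardization is a deliberate
addition: the three channels have incommensurate units, and without it a
Euclidean kNN distance is meaningless; it also makes the features invariant
to global intensity scaling of a scan. Training examples per subject are
the annotated markers dilated by one voxel (3×3×3 windows, deduplicated,
clipped to the grid) as PVS, and a simple random sample of
round(0.10 · |WM ∩ slab|) white-matter slab voxels as background, excluding
foreground voxels (switchable; excluding them reduces label noise).
Probability of a query voxel is the inverse-distance-weighted PVS fraction
among its k = 51 nearest training rows. Numerical rules: all rows tied with
the k-th distance are included (order independence); zero-distance
neighbors dominate (the probability is the PVS fraction among them), which
is the limit of 1/d weighting. One seed drives the background sampling so
leave-one-out runs are exactly reproducible. Neighbor search uses a k-d
tree for large training sets and exhaustive distances for small ones; both
paths implement identical rules and are tested against an independent
exhaustive oracle.

## Seeding

ROI voxels with probability strictly above 0.50 are candidates. Non-maximum
suppression uses the 26-neighborhood for both the maximality test (≥, so
plateaus survive) and plateau connectivity; adjacent survivors provably
share one probability value, so survivor components are plateaus, and each
contributes the voxel nearest its centroid (lexicographically smallest on
ties). 26-connectivity treats all neighbor directions isotropically; the
choice between 6- and 26-connectivity is not externally fixed, and is
recorded here.

## Tubular tracking

From each seed two walks run along ± the local tube axis. Per step,
candidate directions lie on a spherical cap around the current direction:
straight ahead plus 2 polar rings × 8 azimuths. Each candidate is scored by
a tube model after a trial step: score = (μ_in − μ_out)/s, where μ_in is
the mean of trilinear samples on a disc of the trial radius orthogonal to
the direction (rings at 0.5r and r), μ_out the mean on an annulus inside
(r, 2r] (rings at 1.35r and 1.8r), and s a robust spread, 1.4826 × the
median absolute deviation of the annulus samples — a contrast-to-noise
ratio. The spread is floored at 5 % of the global image intensity SD so the
score stays finite and walks terminate on noise-free data; on realistically
noisy images the floor is far below the actual noise spread and inert. The
score is maximized over an 8-point radius grid spanning 0.15–0.70 mm.
Candidates grow a hypothesis tree of depth 3; after each level the 5 best
partial paths by accumulated score are kept (beam search), and the first
step of the best leaf is committed. A walk terminates when the best leaf's
mean per-step score drops below 10, when it exits the white matter or the
volume, or at a hard cap of 60 mm (any such track is removed by the 50 mm
filter anyway).

Two guards address failure modes of greedy tube following. Self-avoidance:
candidates within 2 step lengths of an already committed point (excluding
the 4 most recent, and with the near-seed forward points exempted for the
backward walk) are rejected, so a walk cannot U-turn at a tube end and
re-track itself. Skeleton smoothing: committed points sample the centerline
with direction-quantization jitter of order one step; a 5-point moving
average (≈0.9 mm window at the default step of half the voxel spacing)
removes this jitter while negligibly distorting curvature at the ≥ 10 mm
radii typical of PVS. The search-cap half-angle defaults to 20°, which at a
0.175 mm step still permits a centerline curvature radius of ≈0.5 mm — far
tighter than any physiological PVS — while preventing the walk from
wandering inside wide tubes.

Tracks with L < 2 mm are discarded as false positives and L > 50 mm as
physiologically unfeasible, both bounds inclusive for kept tracks. Seeds
lying within one fitted radius of an already-tracked skeleton are not
re-tracked (non-maximum suppression leaves several seeds along one tube),
and any remaining duplicates — a track whose points lie within one fitted
radius of a longer track for more than half its length — are merged,
keeping the longer track; this addresses repeated detection of long
in-plane PVS. Both behaviours are switchable.

The search depth (3), the "2 angles" (two non-zero polar rings), the
pruning threshold (5, read as beam width) and the termination threshold
(10, read as a minimum mean per-step contrast-to-noise score) follow the
published operating point of this tracker family; the step length, cap
angle, azimuth count, radius grid, score functional, self-avoidance and
smoothing are this implementation's documented choices.

## Agreement metrics

ICC is the two-way, single-measure form: consistency
ICC(C,1) = (MSR − MSE)/(MSR + MSE) and absolute agreement
ICC(A,1) = (MSR − MSE)/(MSR + MSE + (2/n)(MSC − MSE)) for two raters,
computed from the ANOVA mean squares. The point-set Dice coefficient is
made concrete as a maximum-cardinality one-to-one matching with pair
distance ≤ a tolerance radius (default 1.0 mm ≈ 3 reconstructed voxels,
configurable), solved as an optimal assignment rather than greedily;
DSC = 2·|matches|/(|A| + |B|), and two empty sets score 1 by convention.
Bland–Altman limits are mean ± 1.96 SD of the paired differences.

## Atlas maps

Subject→template transforms (4×4 affines or callables over point arrays)
are inputs; registration is out of scope. Density is the number of skeleton
points within 2 mm of each template voxel, averaged over all subjects —
subjects with no points in a neighborhood count as zeros. Attribute maps
dilate each skeleton by 2 mm and average the track attribute voxel-wise
over all covering tracks pooled across subjects ("that area" is read
per-voxel, matching per-voxel rendering of such maps), alongside a support
map of covering-track counts; unsupported voxels carry a background value
(NaN by default).

## Phantom generator

The generator emulates the geometry and noise structure the pipeline
assumes: an isotropic grid (default 128³ at 0.35 mm, the reconstructed
resolution of high-field TSE protocols), a homogeneous white-matter block,
and non-overlapping tubes with radii uniform in 0.15–0.70 mm and lengths
uniform in 3–30 mm. Tube axes lie within a 25° cone of the slab normal,
reflecting that CSO PVS run nearly perpendicular to the axial plane; 60 %
are straight, 25 % circular arcs (curvature radius 20–80 mm) and 15 %
helices (radius 0.3–1.0 mm, pitch 10–25 mm), giving tortuosities in
≈1.0–1.5. Intensities are chosen once as 7 T-TSE-like: T2 white matter 100,
tube (CSF-like) 250, surrounding tissue 80; T1 white matter 120, tube 60;
Rician noise with σ = 5 (SNR ≈ 20 in white matter) and a Gaussian
reconstruction point-spread of 0.5 voxel (T1 is blurred more, reflecting
its lower acquired resolution). Tubes are rasterized by 2× supersampled
occupancy, so sub-voxel tubes produce genuine partial-volume contrast.
Simulated observers mark each tube where it crosses the central slab slice,
with a 10 % miss rate and 0.3 mm marker jitter, so the ICC/DSC machinery is
exercised against known truth. Cohorts draw per-subject tube counts
uniformly from 25–75 (mean 50): agreement statistics over a cohort are
meaningful only if the true counts vary between subjects, as they do in
real populations.

What the phantoms do **not** model: cortical folding and tissue
heterogeneity, vascular trees and branching, lesions, motion and flow
artifacts, coil-profile intensity inhomogeneity, and registration error
between T1 and T2. Passing the phantom suite therefore demonstrates the
correctness of the algorithms under the stated geometric and noise
assumptions, not clinical performance on scanner data.

## Problem sizes and numerics

The acceptance experiment uses 20 subjects at 128³ with 25–75 tubes each —
large enough for stable ICC estimates over a realistic count range while a
full leave-one-out pipeline run stays in the minutes range on one CPU.
Ground truth for count agreement is the number of true tubes whose
centerline crosses the CSO slab, since the automated count is by
construction restricted to the slab. Hessian filtering is done in float64
(float32 leaves ~10⁻⁴-relative kernel artifacts that break the zero-response
and offset-invariance properties); the tracking inner loop is numba-compiled
with trilinear interpolation, and the scalar `tube_score` wraps the same
kernel as the batched tree expansion so the two cannot diverge. All
randomness (phantom geometry, noise, background sampling, observer
simulation) flows from explicit seeds; reruns are byte-identical.

## Known limitations

* Detection is slab-based (2D ROI with 3D tracking), like the visual rating
  scales it mirrors; whole-brain 3D detection is future work.
* The thinnest tubes (radius ≲ 0.25 mm at 0.35 mm grid spacing) often fall
  below the termination threshold's contrast-to-noise bar and are missed —
  the automated count systematically undershoots a permissive observer, as
  expected for a method that ignores structures near the noise level.
* Tube diameter and volume are deliberately not reported: at these
  resolutions they would be dominated by partial-volume error.
* The DSC tolerance radius (1 mm) and the kNN feature standardization are
  package conventions; no external standard fixes them.
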