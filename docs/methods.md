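# Methods

## Measurement model

Each camera of the ring observes the silhouette of an elastic vessel model
as a bright region on a dark background. The analysis treats the silhouette
area as the observable: for camera *c* with per-frame segmented areas
F_ic (px²), the shape deformation factor is n_i = F_ic / F_c, with F_c the
area of the reference frame — the first frame of the sequence, acquired with
the vessel motionless. n_i is dimensionless and independent of the pixel
scale, so it can be compared across cameras, distances and resolutions.

The conversion to millimetres is a modelling choice, since an area ratio
does not determine a unique wall displacement for an irregular contour. We
use the equivalent-circle map: r_ref = sqrt(F_c / π) · s with s the
mm-per-pixel scale at the object plane, and Δr_i = r_ref (√n_i − 1). This is
exact for concentric circular dilation, positive for expansion, and reduces
any silhouette to the displacement a circle of equal area would have
experienced. Whether reported millimetre wall motion of such systems means
radial displacement or diameter change is convention-dependent; this package
reports radial (equivalent-circle) displacement throughout.

Per-cycle amplitudes are max − min of the displacement series within
consecutive windows of one pulse period (60 / pulse_rate seconds; trailing
partial cycles discarded), matching excursion-style reporting of
contraction–relaxation cycles rather than RMS measures. A subject summary
(AWD, average wall deformation) is the mean ± sample SD (n − 1 denominator)
of the 4 positions × 4 probes amplitude table; the n − 1 convention is
verified against the packaged reference dataset, which reproduces only with
sample SD.

## Camera model

Pixel coordinates have their origin at the centre of the top-left pixel,
x right, y down, 0-based. The distortion model is the 5-coefficient
Brown–Conrady form (k1, k2, k3 radial; p1, p2 tangential) applied in
normalized coordinates; this is the minimal standard model covering barrel,
pincushion and tangential distortion. Undistortion inverts the polynomial by
fixed-point iteration (default tolerance 1e-10 in normalized units, max 50
iterations; the tight tolerance keeps pixel-level round-trip error below
1e-6 px across the working field of view). Rectification uses inverse
mapping with bilinear interpolation; out-of-frame samples read as 0, which
is safe under the dark-background assumption. Calibration follows the
plane-based (homography) closed-form initialisation of fx, fy, cx, cy from
≥ 3 views of a planar target, then refines intrinsics, all five distortion
coefficients and per-view poses by Levenberg–Marquardt on the reprojection
residuals; rank-deficient view sets raise a degeneracy error and the final
RMS reprojection error is reported per view.

## Segmentation conventions

Otsu's threshold maximises the between-class variance of the 256-bin
histogram; ties take the smallest maximiser, and foreground is strictly
greater than the threshold. Connected components use 8-connectivity
(4-connectivity would split diagonal necks of noisy silhouettes); the area
is the integer pixel count of the largest component, not the polygon area of
its contour. Component-size ties break by the smallest top-left bounding-box
corner in row-major order. The contour is extracted by Moore border
following (terminated on state repetition, which is robust for one-pixel
bridges and spurs) and is retained for the caliper width — the largest
point-pair distance among boundary pixels, computed via the convex hull —
which serves as the silhouette diameter estimate. No morphological cleanup
is applied by default; optional small-object removal sits behind a
configuration flag and is off in all validation runs.

## Synthetic phantom

The generator emulates the study conditions of a nine-camera ring
(0.70 rad spacing, sweep ±0.70 rad in 0.17 rad steps, object distance
0.30–0.40 m, full HD sensors at 30 fps). One camera's view is rendered as
the vessel cross-section rotated to that camera's ring angle: a boundary
r(θ, t) = base(θ) + a(θ)(1 − cos 2πft)/2 with a Fourier-perturbed base
radius (default 43 mm with small order-2/3 perturbations, matching an
aneurysm sac of ~86 mm diameter), a smoothly angle-dependent amplitude
through four anatomical anchors (default 4 mm, the order of magnitude of
reported AAA wall excursions), pulse rate f = 72 min⁻¹ and 10 cycles by
default. The boundary (256 points) is projected through the full camera
model; the analytic shoelace area of the projected polygon, the area ratio
against frame 0 and the true radial displacement at the view angle form the
ground truth.

Rasterisation is deliberately aliased: a pixel is foreground iff its centre
lies strictly inside the polygon (boundary centres count as outside, making
degenerate edge-through-centre cases deterministic). This makes the
pixel-count area an exact, seed-reproducible quantity that an independent
point-in-polygon oracle can verify, at the cost of realism: real sensors
produce graded boundary pixels. Consequences: (i) grey-level noise (default
sd 2 on levels 200/30) cannot move a silhouette edge, so segmented areas of
a static scene are deterministic; replicate-to-replicate spread in the
square protocol is instead modelled by seeded placement jitter — a lateral
sub-pixel offset plus an independent per-square relative depth error — which
is the physical source of variation between repeat acquisitions of a static
target; (ii) the pixel-count area differs from the analytic area by a
boundary-band term that shrinks roughly linearly with resolution. Photometry
is foreground/background levels 200/30, an optional multiplicative linear
illumination ramp (default 10% across the image) to exercise threshold
robustness, and additive Gaussian noise clipped to [0, 255].

The default working resolution for validation is 480 × 270 (an
aspect-preserving scale of full HD chosen so suites run in seconds); the
default focal length is 0.875 × image width, under which the verification
squares at 0.30 m and 0.35 m rasterise to exact integer pixel sides. The
full 1920 × 1080 geometry is available by configuration. What passing tests
on the phantom do not show: performance on textured, specular or
partially occluded real silhouettes, water-container refraction, or camera
synchronisation artefacts — none of which the generator models.

The "36 angular stations" of the rig are interpreted as the sweep grid:
the 0.17 rad step discretises the ring into floor(2π/0.17) = 36 cells
(nine cameras × nine sweep offsets occupy 81 raw poses, which is not a
self-consistent reading).

## Verification protocol

Two flat squares (0.05 m and 0.10 m sides) are rendered one after the
other, centred and perpendicular to the optical axis, at distances 0.30,
0.35 and 0.40 m; the measurement chain must recover the area ratio 4 (the
first frame is the reference, so the factor of the second frame is the
ratio). Accuracy is reported as the relative-error complement
100 (1 − |measured − expected| / expected), clamped below at zero; the
protocol default of 220 replicates per condition mirrors replicate counts
used with physical rigs and is configurable down for fast runs. The
with/without-water environment is carried as a metadata tag only — the
synthetic imaging path is identical, mirroring the empirical finding that a
water bath does not affect silhouette acquisition.

## Agreement statistics

Bland–Altman analysis reports the bias (mean of paired differences), the
sample SD of differences, and limits of agreement bias ± 1.96 SD; the
half-width 1.96 SD is reported as the agreement interval. The t test is the
classic pooled-variance two-sample Student form (group sizes are equal in
the reference dataset); identical constant samples return p = 1 by
convention, and zero pooled variance with unequal means raises an error
rather than fabricating a statistic. Spearman's rho is the Pearson
correlation of mid-ranks with average-rank ties. All statistics are computed
at full precision and rounded only in reporting (two decimals; four for p).
The packaged dataset reproduces its published per-subject means and SDs
exactly at two decimals; its tabulated p-values are not exactly
recomputable from the printed per-probe values under any standard t-test
variant (the pooled test gives the same qualitative conclusions, p ≫ 0.05),
so tests assert the qualitative statement only.

## Acquisition-queue model

Physical capture used a producer thread feeding two consumers: a lossless
saving queue (bounded only by machine memory) and a size-1 preview queue
whose offers are dropped while the previewer holds a frame. Real threads and
OS priorities are out of scope; the contract is honoured as a deterministic
event-driven simulation (per producer tick: scheduled consumers pop, the
producer appends — raising an overflow error beyond the declared capacity —
and offers to the preview slot). The observable invariants — every produced
frame saved in order, preview occupancy ≤ 1, previews + drops = produced —
are property-tested, and measurements consume the saving path only, so
preview behaviour can never affect results.

## Numerical and design notes

- Problem sizes in the validation suite: 480 × 270 frames, 250-frame
  sequences (10 cycles at 30 fps), 96-point calibration targets with 7
  views, protocol replicates 2–30 in tests.
- Seeding: every stochastic path takes an integer seed;
  replicate streams derive child seeds via `SeedSequence.spawn`, so runs are
  bit-reproducible and replicates independent.
- The deformation factor of the reference frame is exactly 1 by
  construction; non-positive segmented areas raise errors naming the frame
  rather than propagating silently.
- Degenerate inputs: constant images (no Otsu threshold), empty masks,
  sequences shorter than one pulse cycle, and zero expected values in the
  accuracy metric all raise typed exceptions.
- Known limitations: the equivalent-circle millimetre conversion
  under-represents strongly anisotropic wall motion at a single camera; the
  caliper diameter of a rasterised convex shape is biased low by up to one
  pixel; calibration assumes a planar target and no rolling shutter;
  no refraction model for imaging through container walls or water.
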