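# Methods

This note documents the models, numerical choices and limitations of
`pedreg`.  It is written for users who need to judge what the package
computes and what a passing test suite does and does not demonstrate.

## Coordinate conventions

The world frame is right-handed, in millimetres, aligned with the CT
axes: x left→right, y posterior→anterior, z inferior→superior.  The AP
camera looks along +y (source posterior of the patient), the lateral
camera along +x (source on the patient's left).  Pixel coordinates are
0-based with the pixel-centre convention; u indexes detector columns,
v rows.  Poses are six parameters (three rotations in degrees, three
translations in mm); rotations are applied in intrinsic Z-Y-X order
about an explicit rotation centre, by default the centroid of the
landmarks taking part in a registration.  The rotation centre is a
reparameterisation, not a model choice — any rigid map is reachable for
any centre — but pose *parameters* are only comparable between runs
that share a centre, so the simulator records the centre it used and
the pipeline reuses it.

## Projection model

The C-arm is an ideal pinhole projector: point source S, flat detector,
centre of projection P with S→P orthogonal to the detector,
SDD = |SP|.  Projection is implemented in the axis/magnification form
(project the object point onto the central axis, compute
M = SDD/|S→D|, scale the lateral offset), which is algebraically the
ray–plane intersection; the equivalence is enforced by a randomized
property test at 10⁻⁶ mm.  Points at or behind the source raise an
out-of-frustum error.  Points beyond the detector plane (M < 1) are
physically meaningless for transmission imaging but geometrically
well-defined; they project with a warning rather than an error.

No image-intensifier distortion is modelled.

## DRR rendering

DRRs use Siddon's exact radiological path: per ray, the voxel
boundary-plane crossings are merged and sorted, so each voxel
contributes its exact intersection length.  The per-voxel lengths sum
to the geometric chord of the ray within the volume bounding box
(tested at 10⁻⁶ mm); fixed-step sampling is deliberately not used.
Attenuation is μ = μ_water · (1000 + HU)/1000, clamped at zero below
−1000 HU.  μ_water defaults to 0.02 mm⁻¹, a representative value for
effective CT energies of 60–80 keV; it is configurable and rescales all
line integrals jointly, so no geometric result depends on it.  The
unattenuated intensity I0 is 1, i.e. images are transmitted fractions
in (0, 1]; `to_display` maps them monotonically to a [0, 1] radiograph
display.  The renderer is a few seconds per view at the default
160×160 detector on one CPU; rays are processed in vectorised chunks.

DRR intensities are validated by closed-form and property tests
(uniform cube, centred sphere, magnified in-plane shift), never
bit-exactly against clinical images: the source study does not state
its μ_water or beam model, and polyenergetic spectra, scatter and
detector blur are out of scope.

## Registration

The cost is the mean Projection Distance Error over the keyed landmark
correspondences, computed in mm on the detector plane (divide by the
pixel spacing for px).  The optimizer is an in-package CMA-ES —
(μ/μ_w, λ) with rank-one and rank-μ covariance updates, cumulative
step-size adaptation and active (negative-weight) recombination, the
canonical default parameterisation — seeded and fully deterministic.
Population 50 and a 2000-evaluation budget are the framework's stated
operating point; the stop criterion "zero mPDE" is implemented as
mPDE ≤ 10⁻³ mm.  Poses that throw a landmark behind the source receive
a large penalty that grows with the violation.

Two initialisation aids implement the clinical practice of starting
from a projection that already resembles the radiograph:

* `initialize_pose` aligns the projected 3D landmark centroid with the
  2D annotation centroid (demagnified, in-plane translation) and
  matches the RMS spreads of the two clouds (translation along the
  viewing axis).  Rotations start at zero.
* The initial CMA-ES step size is derived per case from the initial
  mPDE: an initial discrepancy of f₀ mm on the detector corresponds to
  ≈ f₀/M mm of rigid motion at the object and ≈ f₀·180/(π·M·ρ) degrees
  for a landmark cloud of RMS radius ρ, clipped to [0.3, 5] mm and
  [0.3, 10/3]°.  A fixed per-parameter search half-width can be set
  explicitly instead (`OptConfig.search_halfwidth`), in which case the
  step size is one third of it.

Both choices matter: with a fixed 5 mm / 3.3° step size the
2000-evaluation budget ends while the residual is still a few
micrometres above the zero-mPDE stop, whereas the discrepancy-scaled
step size lets noise-free registrations actually converge within the
budget.

Single-view registration is weakly identified in depth: translation
along the viewing axis changes the projection only through
magnification, with sensitivity roughly SDD⁻¹ × (landmark spread).
Recovery tests therefore assert in-plane parameters for single views;
depth consistency is exercised where it is observable, in the two-view
triangulation.  `register_vertebra` runs the two views independently
(the clinical procedure; disagreement between the solutions is what
produces nonzero inter-ray gaps) and also offers a joint mode that
minimises the summed mPDE under a single shared pose.

## Trajectory mapping and evaluation

Marker-end annotations are back-projected as infinite lines; each end
is the midpoint of the shortest segment between the AP and lateral
rays, and the line-to-line distance is reported as that end's gap.
Pairs of rays within 0.1° of parallel raise a degenerate-triangulation
error (the closest-point problem is ill-conditioned there); with an
AP/lateral rig the rays are near-orthogonal and far from this limit.
Head/tail correspondence across views is by label; a warning is issued
if swapping one view's labels would shrink both gaps, and if a
triangulated point falls outside a view's source–detector span.

The seven evaluation metrics are 2D-plane quantities: per-view head and
tail displacements (px distance × pixel spacing), per-view acute angle
between the undirected annotated and reprojected marker axes (the
clinical table carries no sign convention), and
|triangulated length − 30 mm|.  Aggregation is the per-field arithmetic
mean; an optional exclusion list supports leaving out levels with known
poor landmark visibility, and no level is excluded by default.  The
published summary for the lateral head end (0.5 mm) matches the
worst-level-excluded mean rather than the full mean (0.68 mm); both are
computed and reported, and neither is asserted as the only valid
aggregation.

## Synthetic phantom

The phantom is built from geometric primitives in Hounsfield units:
vertebral body (ellipsoid, +700 HU) with two pedicles (cylinders,
radius 5 mm) and a spinous process (box), inside a soft-tissue
ellipsoid (+40 HU) surrounded by air (−1000 HU); the marker is a
cylinder of +3000 HU and exactly 30 mm length.  Defaults give an
80×100×60 mm volume at 1 mm isotropic spacing — lumbar-vertebra scale.
The planned trajectory runs through the pedicle centre at a transverse
pedicular angle of 10° (a representative thoracolumbar value), parallel
to the endplates.  The default rig is SDD 1000 mm, source–isocenter
550 mm (magnification ≈ 1.8), 160×160 detector at 1.6 mm pixels — a
C-arm-like geometry whose field of view covers the projected phantom.
The simulated patient pose is a single modest rigid offset
(2°, −3°, 1.5°, 4, −3, 2 mm) shared by both views, as for one physical
patient position under a consistent rig.

Annotation noise is Gaussian in 2D pixels only, drawn independently per
view — imprecise landmark identification on the radiographs, the
dominant error source in practice.  With 0.5 px noise the expected mean
annotation error is σ√(π/2) ≈ 1.0 mm on the detector; registered
residuals settle below this floor because six pose parameters absorb
part of the noise (≈ √(1 − 6/2N) of it for N landmarks).

What the phantom does *not* emulate: realistic bone texture and
low-contrast X-ray appearance, vertebral level ambiguity, occlusion of
the marker by instrumentation, fractured or deformed vertebrae, and
posture-induced deformation between CT and radiographs (handled
clinically by per-vertebra cropping, which is supported but not
stressed).  Passing tests therefore demonstrate the geometric and
algorithmic self-consistency of the pipeline and its noise response,
not clinical-grade accuracy on patient data, where landmark
identification itself is the hard part.

## Problem sizes and determinism

Test and acceptance runs use the default phantom (80×100×60 voxels),
full CMA-ES budgets (2000 evaluations, population 50) per view, a
20-case Monte-Carlo for the noise study, and small detectors for
rendered views; the complete suite runs in about a minute on one CPU.
Every stochastic component (phantom noise, annotation noise, optimizer)
takes an explicit seed, and identical seeds give byte-identical
outputs.

## Known limitations

* Landmarks are given; automatic anatomical or marker detection is out
  of scope.
* Volumes must be on axis-aligned grids (diagonal ±1 direction
  matrices are normalised; oblique acquisitions must be resampled).
* Triangulation uses exactly two views; multi-oblique-view resolution
  is not implemented.
* The evaluation is 2D reprojection-based; no 3D target registration
  error against a planned trajectory, and no breach grading.
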