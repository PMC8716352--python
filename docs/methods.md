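# Methods

This note documents the models, conventions and numerical choices behind
`cbctnav`, and what its synthetic experiments do and do not show.

## Coordinate conventions

World coordinates are LPS (Left–Posterior–Superior, the DICOM patient
convention) in millimetres. Voxel indices are 0-based and map to world
space as `world = origin + direction @ (index * spacing)` with an
orthonormal `direction` matrix whose columns are the index-axis
directions. NIfTI files are RAS by convention, so the I/O layer flips
the sign of the first two world axes on write and back on read; raw
float32 volumes carry the geometry verbatim in a JSON sidecar.

Rigid transforms are proper rotations (det +1 enforced, reflections
rejected) plus translations. The calibration result maps image world →
tool (robot) frame; its inverse is the tool pose in the image.

## Calibration tool and phantom model

The calibration tool is a 200 × 75 × 30 mm plastic slab containing four
hollow spheres whose six pairwise distances are mutually distinct. The
shipped geometry places the spheres (radius 4 mm) at

```
(-27, 8, 11), (16, 8, -4), (24, -29, -4), (-13, 13, -4)   [mm, tool frame]
```

giving pairwise distances 21.1–64.8 mm with a minimum separation of
7.7 mm between any two distances (brute-forced over all 15 pairs; the
model enforces ≥ 5 mm). The in-tool sphere coordinates and diameters of
the physical tool are not published; these values are an invented
default chosen so that (a) the signature gap comfortably exceeds the
matcher's distance tolerance and (b) the posed point cloud fits the
default 192³ × 0.48 mm scan volume (≈ 92 mm cube) with margin under
rotations up to 30°. A seeded random generator of conforming tools
exists for property tests; the shipped set is fixed so downstream
results are deterministic.

Rendering uses HU-like levels: background 40 (water-equivalent),
slab 100, hollow spheres −1000 (air), lesions 120 by default. Sphere
surfaces get a linear partial-volume ramp one voxel wide, which is what
makes subvoxel centroid estimation meaningful. Additive white Gaussian
noise models detector noise; there is no projection-domain simulation,
no beam hardening, no scatter, and no breathing or deformation. The
acquisition protocol of the emulated scanner (200° rotation, 0.5°/frame,
397 projections, 6 s) is carried as inert metadata only — the printed
397 is stored verbatim, never recomputed. When no origin is given the
volume is centred on the posed tool centroid, mimicking a scan volume
positioned over the tool; fiducial or lesion spheres clipped by the
volume boundary raise immediately.

Default lesions: eight 5 mm-radius spheres on a 4 × 2 grid (four lateral
positions × two craniocaudal levels) in the posterior half of the field
of view. The physical phantom's lesion sizes are unpublished, so the
radius is a parameter; it enters only the technical-success criterion
(tip inside the lesion sphere).

## Detection

Candidates are voxels ≤ threshold (dark polarity, default −450: midway
between air and slab) labelled with 26-connectivity — robust for small
spheres at coarse voxel size — then filtered by voxel count (≥ 10) and
equal-volume-sphere radius (1.5–8 mm), which excludes noise specks and
lesions. Centroids are weighted by contrast against the threshold.
`refine_centroid` re-estimates on a local window with the background
taken as the median of the window border; weights below half the peak
contrast are zeroed so a window straddling a material boundary (e.g. a
sphere near the slab face) is not dragged toward the far side. Bright
polarity is supported symmetrically for dense markers.

## Correspondence and rigid fit

Matching enumerates every 4-subset of candidates (capped at the 20
largest blobs; C(20,4)·4! ≈ 116k assignments) and keeps assignments
whose six pairwise distances each match the model within
`dist_tol_mm = 0.96` (two voxel edges: each centroid is good to about
half a voxel, so a distance can err by about one voxel). Survivors are
ranked by post-fit FRE. If a runner-up assignment passes tolerance with
FRE within 1.5× of the best (ratio > 0.67) the match is declared
ambiguous rather than guessed — conservative by design, since the
tool's whole point is that unique distances resolve correspondence. A
degenerate model with duplicate distances (a square) always triggers
this path; `ToolModel` itself refuses such geometry, but the matcher
accepts a bare point array for probing it.

The rigid fit is the closed-form Kabsch solution: SVD of the
cross-covariance of centred point sets, with the smallest singular
direction's sign flipped when needed so det(R) = +1. Collinear input
(second singular value ≤ 1e−8 relative) raises instead of returning an
underdetermined rotation. FRE is the RMS residual at the fiducials; no
TRE prediction model is provided.

## Planning

A unit direction u (LPS) decomposes as craniocaudal = asin(u_z)
(+ = cranial) and RAO/LAO = atan2(−u_x, |u_y|) (+ = RAO, toward the
patient's right); using |u_y| makes both anterior and posterior
approaches read as 0° axial angulation, and a purely craniocaudal
direction returns RAO/LAO = 0 by convention. Reachability is the
inclusive box −32.5° ≤ craniocaudal ≤ 17.5°, |RAO/LAO| ≤ 20°; the
RAO/LAO limit is interpreted as ±20°. Plans within 1° of zero
craniocaudal tilt are classed in-plane (a physical setup never hits
exactly 0°). The guide pose retreats a configurable 20 mm standoff from
the entry point along the trajectory axis so the guide clears the skin.
No collision checking or inverse kinematics is attempted.

## Outcome simulation

The needle-guide robot fixes the trajectory; the residual error model
is:

- two independent transverse angular components θ₁, θ₂ ~ N(0, σ_ang),
  applied as `v ∝ u + tanθ₁·e₁ + tanθ₂·e₂` (exactly recoverable from
  the tip, which the tests exploit);
- insertion depth d = |AB| + N(0, σ_depth), since depth is set by hand;
- procedural time ~ N(μ_t, σ_t) truncated to positive by rejection.

Only outcome statistics of the physical study are available, so the
defaults adopt its observed standard deviations σ_ang = 0.68°,
σ_depth = 1.55 mm, making the simulator's marginals comparable to the
study scale; per-group time defaults are 337 ± 50 s (in-plane) and
380 ± 26 s (out-of-plane), overall 361 ± 43 s. Consequences of this
model, verified by tests against closed forms: longitudinal deviation
is half-normal with mean σ_depth·√(2/π); angular deviation is
approximately Rayleigh with mean σ_ang·√(π/2) ≈ 0.85° at the default.
The study simulator draws 8 in-plane (craniocaudal exactly 0) and 8
out-of-plane (|craniocaudal| ≥ 5°, sampled within 90 % of the limits)
trajectories at 100 mm depth, one pair per lesion.

Because the error model is an assumption, passing tests show internal
consistency and correct geometry/statistics plumbing — not that a
physical robot achieves these numbers. The physically measured study
values are deliberately not reproduction targets.

## Evaluation statistics

C′ is defined as the planned-depth point on the **actual** trajectory,
C′ = A + |AB|·(C−A)/|C−A|, so |CC′| = ||CA| − |AB|| isolates the manual
depth error. The alternative reading — orthogonal projection of C onto
the planned line AB — was rejected because it measures lateral, not
longitudinal, error and would be redundant with the angular deviation.
Planned and actual entry points are treated as identical (justified at
0.48 mm control-scan resolution).

Group summaries use the sample (n−1) standard deviation; a single-value
group reports STD 0 with a `degenerate` flag. The two-group single-
factor ANOVA is computed from sums of squares directly (F = MSB/MSW,
df = 1 and n−2; p from the F survival function); with zero within-group
variance and unequal means it reports F = ∞, p = 0 rather than raising,
and F = 0, p = 1 for identical constant groups. The t² = F identity and
null-p uniformity are covered by tests.

## Wire protocol

Messages use the open image-guided-therapy format, version-1 subset:
58-byte big-endian header (uint16 version, 12-byte type, 20-byte device
name, uint64 timestamp, body size, CRC) with a table-driven,
non-reflected CRC-64/ECMA-182 over the body. Only TRANSFORM (12
float32: rotation columns, then translation) and POINT (136-byte
elements) are implemented — the two messages the workflow needs
(calibration transfer and target transfer). Decoding validates length
and CRC before parsing and re-orthonormalises the float32-rounded
rotation; transport (sockets) is out of scope, file dumps and in-memory
use suffice.

## Problem sizes and determinism

Default test volumes are 192³ voxels (0.48 mm), rendered and calibrated
in well under a second each; the calibration round-trip property uses
100 seeded poses (rotations ≤ 30°, translations ≤ 40 mm, noise SD 15)
and requires 99/100 recoveries within 0.5 mm / 0.5°. Monte-Carlo checks
use 10⁴–2·10⁵ draws, sized so sampling error sits an order of magnitude
below the asserted tolerances. All randomness flows through
`numpy.random.default_rng` with explicit seeds; hypothesis profiles are
derandomised, and `simulate_study`/CLI runs are byte-reproducible for a
fixed seed.

## Known limitations

- Image formation is level-painting plus Gaussian noise; detection
  thresholds tuned here may not transfer to real CBCT contrast, scatter
  or metal artifacts.
- The outcome noise model is stationary and Gaussian; real operator
  error may be depth- or angulation-dependent.
- The matcher is brute-force and capped at 20 candidates; scenes with
  more plausible blobs require stricter detection filtering first.
- The robot side is abstracted to the tool frame: no joint-space
  hand–eye calibration, kinematics or collision model.
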