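# Methods

`fishtrack3d` reconstructs the 3D motion of a swimming fish from
multi-camera high-speed video and derives the resultant forces and torques
on its body by inverse dynamics.  This note documents the underlying models,
the numerical choices, and what the built-in synthetic verification
experiments do and do not demonstrate.

## Body model

The fish surface is a longitudinal series of transverse cross-sections.
Each section is assembled in its local plane from up to three components —
a trunk contour (closed periodic cubic spline through digitised control
points), an optional mirrored pair of eyes (superellipses
|u/a|^n + |v/b|^n = 1), and an optional median fin fold (ordinary
ellipse) — merged by taking the outermost contour of their union
(Shapely polygon union).  Every merged section is resampled to the same
number of circumferential points, starting at the dorsal-most boundary
point and winding counter-clockwise in the section plane, so consecutive
sections stitch into quadrilateral faces.  The two terminal sections
collapse to apex points, closing the surface; the triangulation (apex fans
plus split quads) is watertight, which the mass-property integrals require.

Component parameters are interpolated along the normalised arclength s with
a shape-preserving piecewise cubic (PCHIP), and a component exists only
over the s-range where the spec file defines it.  Defaults: P = 40
circumferential and M = 51 longitudinal points.  The shipped
`zebrafish_larva_5mm.yaml` is a synthetic stand-in whose proportions follow
published early-larva morphology qualitatively (rounded head, lateral eye
bulges, tapering trunk, thin median fin fold over the posterior
two-thirds); its enclosed volume is ≈0.91 mm³, i.e. ≈0.91 mg at the
density of water.  Body models are created separately from the video —
shape is prior knowledge, not estimated from the images.

## Kinematic parameterisation

One frame is described by Ω = (x, y, z, φ_roll, φ_pitch, φ_yaw, κ₁…κ_K):
snout position, Tait–Bryan head angles, and midline curvature at K = 7
control points spaced uniformly over the flexible part of the body (the
anterior 10% is stiff and pinned to zero curvature).  Conventions, fixed
and self-consistent throughout: the head frame has x caudo-rostral (body
towards −x), +y the fish's left, +z dorsal; rotations compose intrinsically
z–y′–x″ (yaw, pitch, roll); positive curvature bends the tail towards the
fish's left.

Curvature is interpolated to the full body with a natural cubic spline and
integrated analytically (exact per-piece antiderivatives) to the local
tangent angle θ(s); the centreline is assembled from segments of exact
length Δs·ℓ along mid-segment tangent directions, so arclength is conserved
by construction and the tangent at each station is exact.  Sections are
carried rigidly: planar, perpendicular to the deformed centreline (pure
lateral bending — no twist, stretch, or out-of-plane bending).  The posed
surface is the bent head-frame surface rotated by R(yaw, pitch, roll) and
translated to the snout.

## Cameras and rendering

The default camera is orthographic: collimated-light shadow imaging makes
magnification depth-independent, so px/mm plus orientation suffice;
perspective pinholes are supported.  The standard virtual rig mirrors the
experimental arrangement: one vertical camera and two side cameras at 30°
elevation, square 15 mm field of view.  Silhouettes are rasterised by a
compiled (numba) triangle scanline: a pixel is set when its centre lies in
a projected facet; back-facing facets are culled (for a closed surface the
front-facing set covers the silhouette).  Pixel origin is the image
top-left, x right, y down.

## Segmentation

Translucent larval fins rule out intensity thresholding, so frames are
segmented on the magnitude of the Sobel intensity gradient: threshold (by
default 0.25 × a near-peak gradient reference, the 99.99th percentile —
a lower percentile would drift into the edge-gradient tail as the image
grows, since edge pixels scale with the perimeter but the pixel count with
the area), morphological closing
(radius 2 px) to bridge noise gaps in the edge ring, hole filling, and
largest-connected-component selection.  The filled gradient band extends
about half its width (≈2 px under 1 px blur) beyond the true silhouette;
a 2 px erosion compensates, which round-trip tests verify at IoU ≥ 0.99
against clean renders.  Illumination flicker is removed by dividing each
frame by its background mean normalised to the sequence maximum.

## Tracking objective and optimiser

Per frame the tracker minimises f_tot = f_GoF + f_reg.  f_GoF counts
pixels in the symmetric difference between rendered and segmented
silhouettes, summed over cameras.  f_reg = ∫ w(s) (dκ/ds)² ds with
w(s) = c₀ e^(−c₁ s) penalises steep curvature gradients, more strongly near
the head; it is evaluated by per-piece Gauss–Legendre quadrature (exact to
rounding for the squared quadratic spline derivative against the
exponential weight).  Defaults c₀ = 100 px²·mm², c₁ = 2: the head is
weighted ≈6× the tail while the tail retains a meaningful penalty — the
tail tip covers few pixels and its curvature otherwise performs a random
walk.  A soft quadratic barrier above |κ| = 8/ℓ keeps curvature
physiological.  Since regularisation cannot distinguish spurious from real
curvature gradients, curvature near the stiff head is expected to be
slightly underestimated.

Optimisation is Nelder–Mead with parameters scaled to comparable units
(1% ℓ, degrees, 1/ℓ): a coarse stage, then a fine stage at ten-fold
reduced tolerances run in cumulative-bend-angle coordinates (a bijection of
the curvature block that decorrelates the silhouette response), then
dedicated low-dimensional refinements of the tail curvature pair and of
the head angles, with the fine/refine cycle run three times per frame
(the third cycle measurably suppresses correlated centre-of-mass wander
during the fastest body motions, which would otherwise leak through the
smoother into the reconstructed forces).  The block refinements matter:
the full 13-dimensional simplex reliably stalls in a shallow, curved
yaw–curvature valley of the integer-valued objective, leaving ~1° yaw and
large tail errors that the low-dimensional searches remove.  Frames are
initialised by least-squares linear extrapolation of the last four states;
the previous solution is kept as a second coarse-stage candidate, rescuing
frames where the motion reverses (e.g. the end of the preparatory stroke).
If the objective jumps more than 30% over the previous frame, restarts from
randomised perturbations (1% ℓ, 5°, 20% of the κ range) are attempted up to
a cap; irrecoverable frames are flagged, not dropped.

## Smoothing and inverse dynamics

Raw tracked parameters are smoothed per parameter with a Whittaker
penalised least-squares smoother with fourth-order difference penalty, so
second time derivatives are smooth; derived quantities are never smoothed
again.  The penalty acts as a low-pass filter with amplitude
1/(1 + λ(2 sin(ω/2))⁸); the default λ places the half-power point at 80 Hz
(≈2× the highest body-wave frequency at 2000 fps), which suppresses
frame-to-frame tracking noise while retaining the swimming kinematics.
GCV-based selection is available but undersmooths when tracking errors are
temporally correlated, which they are.  Sequences are padded by even
reflection before smoothing — the zero-slope boundary is exact for start
sequences that begin at rest and tames the one-sided variance blow-up at
the edges; the first and last five frames are flagged as reduced-accuracy
regardless and excluded from verification comparisons.

The body is assumed homogeneous at the density of water
(ρ = 1000 kg/m³); the surface then determines the mass distribution.
Volume, CoM and inertia come from exact divergence-theorem surface
integrals (trimesh) of the watertight triangulation.  The resultant force
is F = m·a_CoM with a_CoM from second-order finite differences (central in
the interior, one-sided at the ends) of the per-frame polyhedral CoM; the
added mass of the accelerated water is implicitly part of the
reconstructed resultant fluid force.

Because a large fraction of a swimming fish's mass translates over
body-length distances, torque is the time derivative of the total angular
momentum of the deforming body, τ = ρ d/dt ∭ r* × v* dV (r*, v* relative
to the CoM), not I·dω/dt.  The volume integral is evaluated by
partitioning the tube volume into wedge prisms — each circumferential edge
of adjacent rings with the two centreline points — split into three
tetrahedra (an exact partition, unlike signed-tetrahedra decompositions
from an external origin, whose cancellation breaks for non-affine velocity
fields).  Vertex velocities come from finite-differencing the matched
vertex trajectories; within each tetrahedron the velocity field is linear
in barycentric coordinates, for which ∫ λ_i λ_j dV = V(1+δ_ij)/20 makes
the integral closed-form.  This evaluation is exact for rigid motion
(checked against L = Iω) and second-order accurate in mesh size for
bending deformations (checked against a closed-form continuum bending
oracle by Monte-Carlo volume sampling, agreement <1%).

Forces and torques are reported in the world frame and in a fish-aligned
frame: x_fish along the resultant body angle (the local
moment-of-inertia-weighted average of the sectional tangent angles,
weights m_i·d_i² with d_i the slab centroid's distance from the CoM) in the
deformation plane, z_fish the deformation-plane normal, y_fish completing
the right-handed frame; the forward force is the component along the CoM
velocity.  Internally everything is SI; tables report mm, µN and µN·mm.

## Synthetic verification experiments

**Swimming fish.**  The default motion script prescribes, analytically and
C²-continuously: a C-start — curvature pulse A(t)·E(s) with a sin⁴ time
course over 20 ms reaching a peak head–tail angle of 170°, an escape turn
of ~57° yaw, and pitch/roll oscillations of 5–8° — blending (quintic
smoothstep over 16–24 ms) into continuous swimming with a 35 Hz travelling
body wave (wavelength one body length, tail curvature amplitude 4/ℓ), the
snout accelerating to a 0.25 m/s burst.  Frames are rendered at 2000 fps on
the standard rig (≈340 px along the 5 mm fish at 1024²; 512² and 2048²
variants give ≈170 and ≈680 px) and degraded exactly as the experimental
footage motivates: Gaussian blur σ = 1 px, contrast reduced by 45% about
the background level, plus additive Gaussian noise (σ = 5% of maximum
intensity) generated at 10× lower resolution, nearest-neighbour
oversampled and blurred with σ = 5 px, simulating background dirt.  All
randomness is seeded; identical seeds give bit-identical sequences.

Tracking this sequence and comparing with ground truth measures the
end-to-end accuracy (snout and CoM position, head-orientation axis-angle
error, head–tail angle), and feeding both the tracked and the prescribed
states through the identical post-processing pipeline measures the
force/torque reconstruction error with all method-intrinsic biases
cancelled — the same comparison the full-scale verification makes.

**Rigid cylinder.**  A 1.25 mm × 5 mm flat-ended cylinder is driven by
prescribed force and torque profiles; translation integrates with the
trapezoidal rule, rotation with a midpoint rule on the angular momentum
(axis–angle increments from the midpoint angular velocity, with the inertia
tensor rotated to the half-step orientation).  The resulting matched mesh
sequence feeds directly into the inverse-dynamics module (no smoothing);
recovered profiles match the prescriptions to ≪1% RMS of peak away from the
edge frames, validating the dynamics operators in the rigid limit where
closed-form mechanics exist.

**Problem sizes.**  The shipped verification runs use a 48-frame sequence
(24 ms: full C-start plus the blend into the wave) at 1024² for the motion
and dynamics checks, a 14-frame slice through the most demanding phase
(peak bend and unbending) per resolution for the resolution comparison,
and ~100 frames for the cylinder.  These sizes make the whole verification
reproducible on a single CPU in minutes while still covering the
preparatory stroke, the reversal, and the onset of wave swimming.

## What the synthetic tests do not show

The generator shares the renderer, camera model and body model with the
tracker, so model mismatch (an imperfect digitised shape, lens distortion,
refraction, fin-fold deformation, pectoral fins, inhomogeneous density
such as the swim bladder) is not probed; the degradations emulate blur,
contrast loss and background dirt but not motion blur, specularities or
occlusions by other fish.  Accuracy numbers from these experiments are
therefore a lower bound on real-data errors.  Within those assumptions
they verify the complete chain: segmentation, optimisation, smoothing,
mass properties, and the deforming-body angular-momentum integral.

## Known limitations

* Lateral pure bending only: no twist, fin or out-of-plane deformation.
* The simplex optimiser on an integer-valued objective has a shallow
  yaw–anterior-curvature valley; residual yaw errors of ~1° can survive
  even with clean binary data, and curvature near the stiff head is
  systematically underestimated by the regulariser.
* Per-frame optimisation noise, not pixel quantisation, dominates the
  desk-scale error budget during rapid manoeuvres; accuracy gains from
  higher image resolution are correspondingly muted at these sequence
  lengths.
* Homogeneous density; resultant (whole-body) forces and torques only —
  no along-body bending-moment distributions and no fluid-dynamic model.
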