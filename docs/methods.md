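# Methods

## Physical model

A rigid, neutrally buoyant sphere (diameter d ~ 10 um, the size of a
rolling leukocyte or functionalized microsphere) sits near the lower
wall of a shallow perfusion channel (height 2H = 100 um), separated
from it by a gap h that is small compared to the radius in the
adhesion-relevant cases (h = 0.069 um) or moderate (h = 1.4 um for the
12 um lymphoid-cell comparison case).  The carrying flow is steady,
incompressible and, at the wall shear stresses of cell-rolling assays
(0.1-5 dyn cm^-2), firmly in the creeping-flow regime: the particle
shear Reynolds number gammadot d^2/nu stays below 2e-3 x 50, i.e. well
under unity.  The solver therefore treats the steady Stokes equations
as the governing system; the convective term is handled perturbatively
(below), not by a nonlinear solve.

Two ambient profiles are supported, both exact Stokes solutions with
the same wall shear stress tau_w = mu*gammadot at the lower wall:

* **linear** (Couette), u = gammadot*y — the classical Goldman
  assumption of an unbounded constant shear rate;
* **parabolic** (Poiseuille), u = gammadot*(y - y^2/(4H)) — the fully
  developed channel profile, whose curvature lowers both the velocity
  and the local shear rate seen at sphere-centre height
  (by 5% and 10% respectively for d = 10 um in a 100 um channel).

Only the downstream translation u and the spanwise rolling rate omega
are free degrees of freedom; wall-normal migration, lateral drift,
gravity and particle deformability are outside the model.  Sign
conventions: u > 0 downstream, omega > 0 in the forward-rolling sense,
torque reported about the same axis.

## Discretization

The solver is a boundary-integral (Nystrom) method for the single-layer
representation of the disturbance field, using the classical image
system for a point force above a plane so that the no-slip lower wall
is satisfied identically and only the sphere surface is discretized.
The solved density *is* the physical traction up to a uniform-pressure
gauge, so force and torque are plain quadrature sums and the per-facet
pressure / viscous-stress split follows from the normal and tangential
components (the normal viscous stress vanishes pointwise on a rigid
no-slip sphere).

Quadrature grid: a product (theta, phi) grid, graded exponentially in
the polar angle towards the near-wall pole, with cells uniform in
eta = 1 - cos(theta) within each ring so that every cell weight is the
exact cell area.  This makes the total area, the closed-surface
identity sum(n dS) = 0 and the constant-density (rigid translation)
mode exact by construction.  The weak singularity of the free-space
kernel is closed analytically through the identity
int_S G dS = (16 pi a/3) I on a sphere; nearly singular interactions —
the image kernel between gap nodes, and close neighbours generally —
are re-integrated over their source cells with tensor Gauss rules
(8x8 within 3 cell diameters, 4x4 out to 10).  The one-dimensional
nullspace of the closed-surface single layer (density proportional to
the normal, the interior pressurization mode) is removed by a weak
rank-one penalty; it only affects the pressure gauge.

Resolution presets (surface nodes): coarse 28x24 = 672,
medium 56x44 = 2464, fine 72x56 = 4032.  The grading strength is
s = clip(ln(3a/h), 2, 4).  These sizes were fixed from a convergence
study at the hardest geometry (h/a = 0.0138): the stationary-sphere
force and torque change by about 0.1% from medium to fine, and the
motion resistances (which carry the lubrication log terms) by under
1%, approaching the classical near-contact asymptotics
(8/15 ln(1/eps) + 0.96 for translation, 2/5 ln(1/eps) + 0.38 for
rotation) from below.  One LU factorization per geometry serves every
right-hand side (ambient profiles at any shear rate, unit translation,
unit rotation), which is what makes sweeps and mobility solves cheap.

Verified oracles: unbounded-fluid Stokes drag 6*pi*mu*a*U (exact to
machine precision by construction), couple 8*pi*mu*a^3*omega (1e-4),
the uniform traction -3*mu*U/(2a) of the translating sphere
(pointwise), Green's-function identities (zero wall velocity,
solenoidality, reciprocity, momentum balance of the pressure kernel),
and Lorentz reciprocity of the resistance couplings (0.5% at medium).

## Reduced domain and confinement

The companion geometry module reproduces the reduced computational
domain used for volume post-processing: an 80 x 40 um cross-section
whose inviscid (impenetrable, shear-free) side and upper boundaries
bulge smoothly over the sphere so that the cross-sectional area open to
the flow is the same at every streamwise station (within 1e-3; the
bulge amplitude is solved per station from that constraint, with a
0.5 um mollification of the sphere cross-section so the outline is
continuously differentiable).  Because the bulge is constructed
precisely so that the confined field matches the wall-bounded
open-lateral field, the solver does not mesh those boundaries; instead
`domain_sensitivity` quantifies the residual normal flow on them and
converts it, through a source-sheet reflection, into a bound on the
force perturbation.  At the reference conditions this bound is ~0.5%
and it falls with the doubled domain, consistent with confinement
being negligible at blockage ratios of ~2.5%.

## Convective term

`include_convective_term=True` attaches an Oseen-type perturbative
estimate (3/16 Re_a, with Re_a built from the ambient velocity at
sphere-centre height) to the Stokes solution instead of solving the
nonlinear system; above Re ~ 10 the result is flagged as outside the
validated regime.  Across the studied WSS range the estimate stays
below 0.4%, which is the quantitative basis for using the Stokes
default everywhere.  The resistance-matrix pathway refuses the
convective mode (superposition would be invalid); the quasi-static
iteration accepts it.

## Free motion

The force-free/torque-free state solves the 2x2 mobility system built
from three shared-factorization solves.  A damped fixed-point
iteration (`quasi_static_iterate`, default damping 0.7, residual
tolerance 0.5% of the held-fixed loads) mimics quasi-static
time stepping: the imbalance is scaled by the unbounded drag
coefficients, so near the wall the effective relaxation factor is
below one and the iteration contracts, typically in 15-30 steps; it
agrees with the mobility solution to the residual tolerance and exists
both as a cross-check and as the pathway that tolerates the
convective estimate.

## Goldman reference factors

The Goldman-model values (linear profile, single wall, Stokes) are
produced from a bundled table of dimensionless wall-correction factors
F*, T*, U*, W* over eps = h/a in [0.005, 10], computed with this
package's own linear-mode solver at fine resolution and interpolated
monotone-cubically in log(eps); the grid includes the gap ratios of
the bundled presets, so those evaluate without interpolation error.
Near contact the stationary factors plateau at F* ~ 1.70 and
T* ~ 0.944, the classical lubrication limits; at large eps they
approach the free-sphere values (1, 1, 1, 1/2).  Published tabulations
of these factors exist only at a handful of gap ratios, and published
comparisons built on them interpolate a logarithmically slow function
across wide gaps in eps; self-computed factors at the exact geometry
are typically 3-6% above such interpolated values for the free-motion
quantities, which is the main source of deviation in the free-motion
comparison rows (see the report module's deviation columns).

## Synthetic Janus videos

The generator renders volume-dyed fluorescent spheres half-coated with
an opaque cap, viewed orthographically from above at 25 frames/s on a
480 x 250 grid of 1.3 um pixels (a 2x2-binned 960x500 sensor; the
pixel pitch is a configurable calibration, not a measured constant).
A pixel is bright when the near surface at that pixel is uncoated, so
the projected bright area follows the moon-phase law
A(phi) = A_disc (1 + cos phi)/2, one cycle per revolution, vanishing
briefly when the cap faces the camera.  Rendering is supersampled 4x
and Gaussian pixel noise is added; rotation rates at or above the
temporal Nyquist limit pi*fps are refused.

The tracker mirrors the experimental procedure: threshold, contour
label, minimum-enclosing-circle diameter with a 5 um gate,
frame-to-frame association by forward displacement under half the
particle diameter within +/-15 degrees of the flow axis for young
tracks, and predicted-footprint overlap with a look-ahead window
(default 12 frames) for established tracks — the look-ahead is what
carries a track across the dark phase of each revolution.  Positions:
the minimum-circle centre is phase-stable and anchors association;
the intensity-weighted centroid, whose oscillation around the particle
centre cancels over full revolutions, feeds the total-tracked-distance
velocity estimate.  Rotation is the dominant spectral period of the
projected-area series (zero-padded FFT with parabolic peak
interpolation), cross-checked against peak counting with a minimum
peak separation of 60% of the spectral period; tracks shorter than two
cycles or without area modulation return a no-estimate flag.

What the generator does *not* emulate: photobleaching, depth-of-field
and focal asymmetry, motion blur (the exposure setting is metadata
only), Brownian jitter, polydispersity, and out-of-plane rotation of
the coating axis.  Recovery tests on this generator therefore
demonstrate the estimators' correctness under the stated image model,
not their robustness to every real-microscopy artefact.

## Numerical parameters at a glance

| parameter | default | meaning |
|---|---|---|
| resolution | medium (56x44 nodes) | surface quadrature preset |
| grading s | clip(ln(3a/h), 2, 4) | polar clustering strength |
| near_factor / near_subdiv | 10 / 8 | near-field re-integration reach and order |
| BC residual | < 1e-8 (direct solve) | discrete boundary-condition residual |
| free-motion residual | 0.5% of held-fixed loads | mobility / iteration tolerance |
| damping | 0.7 | quasi-static relaxation factor |
| pixel pitch | 1.3 um/px | image calibration after 2x2 binning |
| look-ahead | 12 frames | association bridge across dark phases |

## Known limitations

* The single-wall image system neglects the second channel wall
  (95 um away for the 10 um sphere: a sub-0.5% effect) and treats the
  reduced domain's inviscid boundaries perturbatively rather than
  exactly.
* Near-contact motion resistances converge slowly (lubrication log
  terms); below eps ~ 0.005 the bundled table should not be
  extrapolated.
* The parabolic-profile effect computed here is a few percent on force
  and torque (curvature of the ambient profile over the sphere), and
  the free rolling rate always stays below half the local ambient
  shear rate — a rigorous property of wall-hindered torque-free
  spheres in this model.  Published comparison values that exceed such
  bounds cannot be matched by any resolved computation of this model;
  the report module prints the deviations rather than hiding them.
* The video pipeline assumes one particle per association window;
  dense fields of overlapping particles are not handled.
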