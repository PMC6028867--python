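# Methods

`torquecell` predicts the removal torque of a cylindrical implant from the
mechanics of a single surface feature.  The model has two stages: a
microscopic unit-cell fracture simulation of one roughness-derived conical
feature sheared against the polymer it is embedded in, and an analytic
macroscopic torsion layer model that scales the unit-cell reaction forces up
to implant torque.  This note records the model assumptions, the parameters
that matter, the numerical choices, and what the verification suite does and
does not establish.

## Surface model

The acid-etched implant topography is idealized as one right circular cone
(base radius `a`, height `h`) protruding from a flat plane, repeated
periodically with the unit-cell footprint (default 3.15 × 6.3 µm).  Three
areal roughness parameters characterize the target surface: the arithmetic
mean deviation Sa, the RMS slope Sdq (expressed as an angle), and the
developed area ratio Sdr.  For this geometry all three have closed forms;
notably the RMS gradient of a single cone in a cell of area `A` is
`h·sqrt(π/A)` — independent of the base radius — so an Sdq target alone pins
the feature height.

Cone dimensions are obtained by `fit_cone` in one of three modes: match
Sa+Sdq exactly, match Sdq+Sdr exactly, or least-squares over all three.  A
single cone has two degrees of freedom, so all three parameters cannot in
general be matched at once; the achieved triple is always reported next to
the targets.  For the packaged acid-etched benchmark (Sa 849 nm, Sdq 50°,
Sdr 40%) the Sdq+Sdr pair is the feasible and physically preferred choice —
slope and developed area are the quantities that drive mechanical
interlocking — and it yields `a = 1.2765 µm`, `h = 2.9953 µm` with an
achieved Sa of 393 nm.  The Sa+Sdq pair is *infeasible* for this cell: with
`h` fixed at 2.995 µm by the slope target, the largest base circle that fits
the footprint (a = 1.575 µm) reaches only Sa = 515 nm.  `fit_cone` raises an
explicit infeasibility error naming the violated bound in that case, and the
test suite documents (by a 2000×2000 grid search) that no single cone in
this cell comes within 10% of all three targets simultaneously.  This is an
inherent limit of the single-cone idealization, not of the fitting.

Height-map roughness uses central differences (one-sided at borders) for the
gradient and a two-triangle facet split per grid quad for the developed
area; closed form and a 2048² rendered map agree within 0.5%.

## Micro model

The polymer block occupies the unit-cell footprint down to a configurable
substrate depth, with the conical imprint of the feature in its top surface
(z is depth into the polymer; the interface plane is z = 0).  Material: homogeneous
isotropic linear elastic, E = 3.76 GPa, ν = 0.34, with a von Mises fracture
threshold of 40 MPa.  The titanium feature is treated as a rigid master
surface (modulus ratio ≈ 30); titanium constants are kept in the
configuration for a deformable-master variant.

**Mesh.** Structured first-order hexahedra, body-fitted by a
terrain-following mapping: inside a uniform band reaching two element sizes
below the feature tip, each node column is squeezed between the local
imprint surface and the band bottom, so the top node sheet lies exactly on
the imprint.  Below the band the layer height grows geometrically (ratio
1.5, deepest layer absorbing the remainder), which makes the near-interface
mesh bit-identical for every substrate depth — a prerequisite for a clean
boundary-distance convergence study — at a cost of a few smooth far-field
layers.  Mesh adequacy is judged by the volume criterion: the FE volume must
match the CAD volume (box minus cone) to 1% (0.03% at the default element
size).  Default element size 0.4 µm ≈ 1/3 of the cone radius, chosen so a
full gap sweep runs on one CPU in minutes; the element count at the bench
geometry is then ≈ 2000.

**Boundary conditions.** Bottom face clamped; the two faces normal to the
enforced direction are tied pair-wise (exact master–slave merging of
matching nodes — the periodic "continuous" condition); the transverse faces
are fixed in their normal component only.  Tying is exact elimination, not
penalty.

**Contact.** Frictionless unilateral contact of polymer nodes against the
rigid master, which is the cone offset *inward* by the interfacial gap
(10–150 nm): a uniform normal clearance, as a debonded cast imprint would
leave.  The master repeats with the cell pitch along the enforced direction
so large translations wrap periodically.  The signed-distance field of the
offset cone is exact (meridian-plane projection); contact is enforced by
penalty springs along the surface normal with an active-set fixed point:
springs on currently penetrating nodes, recomputed normals each iteration,
two-cycle oscillations broken by biasing toward the union set, convergence
when the displacement field is stationary and the active set stable.
Penalty stiffness defaults to `100·E·h_elem` and escalates tenfold (up to 3
times) if the maximum penetration exceeds `1e-3` element sizes.  The solver
was verified against exhaustive dense enumeration of all active sets on a
small fixture.  Every node of an active element is a contact candidate, so
newly exposed surfaces after element deletion keep interacting with the
master (eroding contact).

**Fracture.** Element death: an element whose von Mises stress (volume-
averaged over its Gauss points; max-over-points available as an option)
reaches 40 MPa is deactivated and its stiffness removed; nodes left without
active elements are clamped.  Deletion is simultaneous per pass, and each
solve–delete pass repeats until a pass deletes nothing.

**Stepping.** The protocol records six equal displacement increments.
Internally each increment is applied in sub-increments (default 20 nm) with
the fracture loop inside, because a micrometre-scale increment in a single
linear solve drives contact stresses two orders of magnitude past the
threshold and deletes the entire block in one unphysical cascade; gradual
advance lets the stress field re-equilibrate after every deletion, the
quasi-static analogue of a dynamic solver's continuous erosion.  Before each
deletion the yield trigger is located by stress-targeted regula falsi in the
master displacement (the element stress is nearly linear in the displacement
at a fixed contact set; iteration stops when the peak stress exceeds the
threshold by less than 1%), so the recorded pre-fracture force peaks are
independent of the sampling phase and of the overall system stiffness — a
displacement-tolerance rule would bias the recorded peaks by an overshoot
proportional to the system stiffness, which varies with substrate depth.
At each trigger the curve records both the
pre-fracture tooth tip and the post-fracture drop (two samples separated by
an infinitesimal displacement), so piecewise-linear interpolation reproduces
the full sawtooth rather than clipping the teeth; the six protocol stations
are flagged in a column.  The reaction force is the x-component of the total
contact force the polymer exerts on the master, reported positive when
resisting the motion.

The base stiffness factorization is reused across sub-increments and contact
iterations (it changes only when elements are deleted); the rank-m penalty
update is applied through the Woodbury identity with one batched triangular
solve per iteration.

**Total displacement.** Not an independent parameter: it is the macroscopic
top-layer displacement at the maximum rotation of the torque grid (below),
so the micro curve spans exactly the displacements the combination samples.

## Macro model

The cylinder (3 mm diameter, embedded 9 mm, bottom cross-section fixed) is
an elastic shaft in torsion: twist linear in height, so the tangential
surface displacement of layer j (20 layers of 0.45 mm, evaluated at mean
height) is `u_j = r·Θ·z_j/L`.  At Θ = 0.1° this gives a 2.62 µm
top-to-bottom difference and 0.13 µm between successive layers.  The removal
torque is

    T(Θ) = Σ_j r · (π·d·h_layer / A_cell) · F_micro(u_j(Θ)),

with `F_micro` the piecewise-linear interpolation of the micro curve
(clamped, with a warning, beyond its last sample) and `π·d·h_layer / A_cell
≈ 2.14e5` the per-layer area upscaling.  The macro stage is purely analytic;
no FEM.  One micro curve (per gap size) serves all layers.

**Rotation grid.** Default 0–0.12° in 0.0005° steps — the step is chosen so the top layer's displacement per rotation sample (≈ 13 nm) resolves the micro curve's sub-increment scale; a coarser grid aliases the sawtooth and scatters the per-layer peaks across teeth.  The 0.1° scale is where
the model's own kinematics place the interfacial displacements at the
feature scale (≈ 3 µm at the top layer); degrees-scale rotations would push
the unit cell an order of magnitude past its feature size, outside the
model's meaning.  Grid and maximum are configurable.

## Verification and convergence

The suite verifies: element stiffness against a finite-difference Hessian
of the quadrature strain energy and its six-mode rigid-body nullspace; patch
tests (constant stress exact to 1e-9); uniaxial stress `σ = E·ε` exact; a
40×4×4 cantilever within 10% of Euler–Bernoulli (shear flexibility and
full-integration stiffness account for the residual); contact against the
exhaustive active-set oracle; Newton's third law via support-reaction
bookkeeping; penalty insensitivity (<1% under a tenfold penalty change);
fracture timing on a single element against the Hooke's-law hand
calculation; softening (deletions never increase the force at fixed
displacement); determinism (bit-identical reruns — the pipeline contains no
randomness).

**Substrate depth.** The depth below the feature is validated by convergence
analysis of the peak micro reaction force under depth doubling, holding the
near-interface mesh fixed.  A probe of the elastic phase shows the force
at equal peak stress is depth-invariant to < 1% per doubling; in the full
fracture run, doubling the default 6 µm depth (twice the feature height)
changes the resolved peak force by 1.7%.  The default substrate depth is
therefore 6 µm.

## What the benchmark does and does not show

The synthetic benchmark reproduces the *mechanism*: reaction forces that
fall with successive fracture passes, gap sizes that reduce contact area,
fractured volume and peak torque monotonically, and loosening that
propagates from the top layer downwards (the top layer is always the first
whose contribution passes its peak).  Peak torques come out at the
newton-centimetre scale of bench removal-torque tests.  It does not
reproduce: absolute torques of any specific experiment (the single-cone
idealization underestimates Sa by construction, and the true etched surface
has multi-scale features and pits); adhesion or friction (the interface is
frictionless and non-adhesive, so only mechanical interlocking resists);
bone's anisotropy and viscoelasticity; screw-shaped geometries.  Force
curves are sawtoothed by discrete element death; quantities compared across
configurations should be trigger-resolved peaks or integral measures, both
of which the curve object provides.

## Numerical parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| element size | 0.4 µm | uniform in-plane / band size; volume criterion 1% |
| substrate depth | 6 µm | validated by the depth-doubling ladder (<2%) |
| penalty factor | 100 | `k_p = 100·E·h_elem`, escalation ×10 up to 3× |
| penetration tol | 1e-3·h_elem | contact feasibility requirement |
| sub-increment | 0.02 µm | fracture-loop displacement resolution |
| trigger tol | 1% of σ_y | stress window for locating the yield trigger |
| outer steps | 6 | recorded protocol stations |
| fracture passes | ≤ 20 per trigger | cap on the delete–resolve loop |
| gap sweep | 10, 50, 100, 150 nm | interfacial clearance conditions |
| rotation grid | 0–0.12°, step 0.0005° | resolves the micro curve at the top layer |

Degenerate inputs are rejected at construction: negative gaps, cones not
fitting the cell, offset gaps that collapse the cone (gap ≥ meridian
inradius), element sizes not resolving the feature, inverted elements,
conflicting constraints.  Ties in `peak_torque` resolve to the smallest
rotation.
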