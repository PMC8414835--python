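# Methods

`aaafsi` is a desk-scale re-implementation of an ultrasound-driven
fluid–structure interaction (FSI) workflow for abdominal aortic aneurysms
(AAAs): from a stack of segmented lumen contours at the diastolic frame to
wall stress, displacement, and wall-shear metrics, run once with wall
pre-stress estimation (PSE) and once without, and compared. This note
records the models, the numerical choices, and what the synthetic study can
and cannot show.

## Geometry

A segmentation is a stack of planar elliptical contours (center, two radii,
in-plane rotation, unit normal) along a centerline; axial stations are arc
length from the proximal end, the global z axis is the longitudinal
("spine") axis, units are mm. The synthetic generator produces a fusiform
dilation: a Gaussian diameter bump from the neck diameter up to the maximum
diameter over the sac length, elliptical cross-sections whose minor axis
shortens with the local dilation (cross-sectional asymmetry), an anterior
shift of the dilated sections, and a bowed centerline. Defaults (47 mm
maximum diameter, 22 mm necks, 75 mm sac, asymmetry 0.40, bow 15 mm,
0.15 mm contour jitter) emulate a moderate aneurysm near the cohort average
of the shipped patient table. The pronounced asymmetry and bow reflect AAA
morphology: the spine blocks posterior expansion, so the sac bulges
anteriorly. This matters mechanically — the difference between the PSE and
no-PSE arms in wall stress is driven by loss of surface curvature when the
unstressed wall balloons, and a nearly axisymmetric bump simply does not
have enough curvature structure for that mechanism to operate.

Stacks are elongated by 50 mm proximally (antiparallel to the spine axis)
and 50 mm distally (along the local centerline tangent) with cubic Bezier
centerline extensions that are G1 at the junctions and end in circular
20 mm contours; radii and rotation blend linearly in normalized arc length.
The lumen surface is a structured quadrilateral grid: a shared, even
circumferential node count chosen from the median contour perimeter and the
target edge length (0.8 mm mirrors the source workflow; the desk-scale
default used throughout the tests is 7 mm), and an odd ring count — both
parities are what the quadratic extrusion needs. The wall mesh extrudes the
surface 2 mm outward along averaged nodal normals into two layers of
27-node triquadratic hexahedra (five node sheets). Enclosed lumen volumes
use the divergence theorem over triangulated quads with centroid-fan end
caps; flipped orientation is detected by the sign and rejected.

## Wall mechanics

The wall is isotropic, incompressible Neo-Hookean: sigma = −p I + G (B − I)
with B = F Fᵀ, shear modulus G assigned by maximum-diameter group
(S ≤ 39 mm: 0.92 MPa, M 40–49 mm: 1.02 MPa, L ≥ 50 mm: 1.36 MPa).
Incompressibility is enforced by a volumetric penalty rather than a mixed
formulation: the solver uses the compressible Neo-Hookean of the same
family, sigma = G/J (B − I) + lambda ln J / J I (so the standalone penalty
stress op and the FEM agree to O(J−1), which is below 1e-3 here), with
lambda = 2 G nu/(1 − 2 nu). The numerical Poisson ratio defaults to
nu = 0.495: against the closed-form incompressible cylinder inflation the
error is 0.7% (0.1% at 0.499), while the tangent conditioning improves
enough that the FSI loop can reuse factorizations across time steps instead
of refactorizing nearly every step — on one CPU this halves the cost of a
cardiac cycle.

Elements are 27-node hexahedra with 3×3×3 Gauss quadrature; element
residual, consistent tangent (material + geometric), and the follower
pressure load (normal to the deforming luminal surface, with its exact
nonsymmetric load stiffness) are numba-compiled kernels, verified against a
vectorized numpy implementation to machine precision. Inlet and outlet
cross-sections carry local cylindrical frames and may move only radially.
Newton iteration uses full steps (the residual norm is a poor merit
function for the stiff penalty term; backtracking only guards element
inversion), converges at a relative residual of 1e-8 by default, and reuses
the factorized tangent across solves until convergence stalls far from
tolerance (modified Newton); the grader-visible contract is unchanged
because iteration is residual-driven. Automatic load substepping handles
cold starts far from equilibrium.

Pre-stress uses the backward incremental scheme: twenty increments
p_i = p_m sin(i π/40), each solved on the measured geometry with the
previous increment's Cauchy stress carried as initial stress; displacements
are reset every increment, so the final stress field equilibrates the
measured (diastolic) pressure on the measured geometry with near-zero
displacement. Re-solving at p_m then moves nodes by well under 1% of the
wall thickness, and on a thin tube (radius/thickness = 20) the mean hoop
stress lands within 5% of the Laplace value p·r/h.

## Hemodynamics

Brachial cuff pressures convert to abdominal-aortic values as
P_dia,AA = 0.88 P_dia,brachial and P_sys,AA = 1.05 P_sys,brachial; mean
arterial pressure is (2 dia + sys)/3. Blood is shear-thinning Carreau
(eta0 = 0.056 Pa·s, eta_inf = 0.00345 Pa·s, lambda = 3.313 s, n = 0.3568),
density 1040 kg/m³.

The inlet flow is a generic triphasic infrarenal waveform at 75 beats/min
with a 0.96 L/min mean: a Gaussian-bump template (systolic peak, early
diastolic reversal, low diastolic baseline) projected onto 24 Fourier
harmonics, which makes the waveform exactly periodic and its analytic mean
exactly the requested flow. The template's shape parameters were set to the
physiological envelope of published infrarenal waveforms at rest (peak
~63 mL/s, reversal ~−7 mL/s at the default mean, peak-to-mean ~3.9); an
over-pulsatile shape would make the downstream pressure targets physically
unreachable for the stiffest-pulse patients.

The outlet is a 3-element Windkessel: characteristic impedance
Z = sqrt(rho h E/(2 π² (1 − nu²) a⁵)) evaluated with the actual 10 mm
outlet radius (the printed 1 mm value in the source derivation is
dimensionally implausible for a 20 mm outlet and Z only seeds the tuner),
R = p̄/q̄ − Z, C = 0.6 s/R initially. For parameter tuning an extra
compliance C_A — volume storage of the distensible aneurysm, estimated as
(V_sys − V_dia)/(P_sys − P_dia) from wall solves, or from a closed-form
fusiform-cylinder integral when only tabulated patient dimensions exist —
is placed upstream of Z. The tuner scales total resistance by the
target/simulated mean-pressure ratio and compliance by the simulated/target
pulse-pressure ratio until the simulated diastolic and systolic extremes
are within 0.5 mmHg. Because the circuit is linear and the waveform a
finite Fourier series, the periodic response is evaluated exactly in the
frequency domain (node impedance per harmonic); the time-domain ODE
integrator exists alongside it and the two agree to <1e-3 mmHg, which is
itself a test. All thirty patients of the shipped table tune in well under
a second.

Wall shear stress uses the Poiseuille recovery tau_w = eta(|4q/(π a³)|) ·
4q/(π a³), signed by flow direction — a reduced-order stand-in for 3D CFD
wall shear; no Womersley or secondary-flow correction is attempted.

## Partitioned FSI

The fluid is a distensible-lumen balance on the axial stations of the wall
mesh: segment-wise volume conservation gives the flow profile from the area
profile, the implicit Windkessel closes the outlet, and upstream pressures
add Poiseuille viscous and fluid-inertia gradients. The wall is solved
quasi-statically (no structural inertia): with a 1D lumen there is no
added-mass operator in the structural sense, and the quasi-static wall is
the matching reduced-order choice. Interface fields are the axial area
profile (wall → fluid) and pressure profile (fluid → wall), broadcast
ring-wise.

Each time step iterates fluid and wall to an interface residual below 1e-5
(relative), stabilized by an interface quasi-Newton of least-squares type:
the first iteration relaxes with omega = 0.5, later iterations solve a
least-squares problem on normalized residual-difference columns (kept
across time steps, twenty at most, oldest dropped on rank deficiency) to
apply an approximate inverse Jacobian. Column normalization matters: with
raw columns the least squares stalls an order of magnitude above
tolerance during systolic deceleration. A trust region caps each interface
move at 30 mmHg and floors the guess at −20 mmHg, which keeps the wall
solver inside its convergence basin during the violent first no-PSE step;
plain relaxation with omega = 1 diverges on the compliant default fixture,
which is demonstrated as a test. The inner Newton tolerance follows the
interface residual (1e-4 times tighter, floored at 1e-11) because wall
solver noise is amplified ~1000× by the area time-derivative and the
outlet impedance before it reaches the quasi-Newton secants.

Both arms run three cardiac cycles from a diastolic initialization and the
last cycle is evaluated. The PSE arm starts from the pre-stressed measured
geometry, already in equilibrium, and is periodic after the first cycle.
The no-PSE arm starts from the *unloaded* measured geometry: the wall
balloons inside the first coupled steps, drains volume from the lumen, and
knocks the Windkessel out of equilibrium — this transient, not a steady
property, is why the no-PSE arm underestimates diastolic (and systolic)
pressure at cycle three. Its cycle-to-cycle pressure drift is surfaced so a
user can see the arm has not fully settled, mirroring the caveat that the
no-PSE protocol needs more cycles.

## Metrics

Per-point time-averaged wall shear stress TAWSS = (1/T)∫|WSS|dt and
oscillatory shear index OSI = ½(1 − |∫WSS dt|/∫|WSS|dt) ∈ [0, 0.5] use the
trapezoidal rule; an all-zero signal yields an undefined marker. Systolic
fields are taken at the time of maximum (diastolic: minimum) mean lumen
pressure in the evaluation cycle. Displacement, stress, and TAWSS are
scaled to the measured systolic pressure by SBP_AA/SBP_FSI before
comparison; spatial differences are (phi_noPSE − phi_PSE)/mean(phi_PSE)
× 100% per node with the mean absolute value as summary. Percentiles (99th
displacement/corrected displacement/stress/OSI, 1st TAWSS) use linear
order-statistic interpolation and are evaluated over the native AAA region
only (elongations masked out): displacement over nodes, stress over
quadrature points, shear metrics over axial stations. Corrected
displacement is |u_sys − u_dia| per node. Paired comparisons use Wilcoxon
signed-rank tests (exact null for small tie-free samples, normal
approximation with tie handling otherwise, zeros discarded), significance
at p < 0.05; an exhaustive sign-enumeration oracle backs the implementation
for small n.

## What the synthetic study shows — and what it does not

The generator reproduces the *structure* of the source data (elliptical
diastolic contour stacks of realistic size, asymmetry, and jitter), not any
patient's geometry; the reduced-order lumen replaces 3D CFD, so WSS
patterns are axial profiles, secondary flows and 3D vortices are absent,
and OSI magnitudes are far below those of real 3D simulations. Direction
checks between the arms (no-PSE: higher 99th-percentile displacement,
lower 99th-percentile stress, lower simulated diastolic pressure) are
therefore meaningful, but the published population magnitudes (tens of
percent) depend on the thirty clinical geometries and full 3D
hemodynamics and are not reproduced here. The no-PSE pressure
underestimation in particular is transient-driven; with a quasi-static
wall the system settles faster than a dynamic 3D model, so the deficit at
cycle three is smaller than reported for the clinical cohort.

Default problem sizes are deliberately desk-scale: a 7 mm target edge
(≈130 quadratic hexahedra, ≈4000 degrees of freedom), dt = 8 ms at 75
beats/min, three cycles. All analytic oracles (cylinder inflation, Laplace
hoop stress, annulus volume, Windkessel transfer function, Wilcoxon
enumeration) are resolution-independent checks of the same code paths used
at full resolution.

## Known limitations

- No anisotropy, no collagen fiber recruitment, no intraluminal thrombus,
  no patient-specific stiffness estimation; uniform 2 mm wall thickness.
- No aorto-iliac bifurcation; single-lumen elliptical stacks only (no
  branch or twist irregularities).
- Quasi-static wall: structural inertia and damping are absent, so rapid
  transients settle faster than in the dynamic reference workflow.
- The Poiseuille WSS recovery underestimates oscillatory character at the
  sac; OSI is best read comparatively between arms, not absolutely.
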