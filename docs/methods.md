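# Methods

`tmjfem` re-implements, as a tested library, an image-based workflow for the
patient-specific biomechanical analysis of a custom temporomandibular-joint
(TMJ) prosthesis: CT calibration and segmentation, Hounsfield-unit-based
material mapping, voxel meshing into quadratic tetrahedra, linear-elastic
solves with bonded and frictional-contact couplings, normalized von Mises
comparison of model variants, and ISO-14243-2-style wear-rate estimation.
Because the clinical inputs of such a study (patient CT, manufacturer CAD,
physical wear specimens) are never distributable, every stage runs on a
seeded synthetic phantom whose ground truth is known exactly.

## The phantom

The phantom emulates a post-operative mandible CT: a stack-of-slices scalar
volume with isotropic 0.3 mm voxels (default grid 120 x 120 x 90, about
36 x 36 x 27 mm). Its geometry is parametric, not anatomical — acceptance
is property-based, so what matters is that each downstream stage sees the
structures it must handle:

* a horseshoe (torus-sector) **mandible body** with a cortical shell
  (nominal 1400 HU) over a trabecular core (300 HU), two rami, a natural
  condyle on the contralateral side and a resected stump on the treated
  side;
* **teeth** as dentin cylinders (1700 HU) with enamel caps (2500 HU),
  rooted in the bone;
* a titanium (3100 HU) **prosthesis plate** with condylar head, fixed by
  three screws that pass through the plate into the ramus, plus two
  optional planning-stage "dummy" screws that attach to the plate but reach
  no bone;
* water-equivalent soft tissue (0 HU) and air (-1000 HU), with small
  water/air sample regions recorded for two-point calibration.

The prosthesis and screws are rasterized from exact triangulated surfaces
(the stand-in for manufacturer CAD), and those same surfaces are emitted as
ground truth, so the segmented and CAD-based model variants share one
geometry and the surface-deviation stage has an exact reference. Raw voxel
values are `raw = g*HU + h` (defaults g = 0.5, h = 1024) plus seeded
Gaussian noise in HU; `g`, `h` are stored in the truth record so the
calibration stage inverts a real transform. All dimensions scale with the
physical volume extent, so tests can shrink the grid without losing parts.
Identical seed and configuration give bit-identical outputs.

What the phantom does **not** emulate: partial-volume blur, beam hardening
and reconstruction kernels, anatomical shape variability, and soft-tissue
heterogeneity. Tissue voxels carry their pure nominal HU plus white noise.
Consequently a Dice of 1.0 on the noise-free phantom shows the chain is
*exact where exactness is possible*, not that it would segment a real scan
perfectly; the seeded-noise case (sigma = 30 HU, a realistic clinical noise
level and the default study condition) probes robustness of the
threshold-plus-morphology chain, not of partial-volume handling.

## Segmentation

Calibration maps the mean raw value of a water region to 0 HU and of an air
region to -1000 HU by the unique affine map through those two points.
Masks are range selections at the midpoints between nominal tissue HU
values — the reproducible stand-in for an operator-tuned adaptive
threshold; a genuine Otsu-style adaptive split is available and tested.
Per-mask bounding regions (boxes around each tooth; tight per-component
boxes from the posed CAD surfaces for the metal parts) play the role of the
operator's region restriction. Cleanup applies, in priority order: island
removal (26-connected components below a voxel count), cavity fill
(6-connected enclosed background; the standard dual connectivity pair), and
morphological closing. Closing defaults off in the phantom workflow: with
pure-tissue voxels the thresholds are already exact and a radius-1 closing
would fill staircase concavities of correct masks; it remains available for
real data. Mask priority at label assembly is prosthesis > screws > dummy
screws > teeth > mandible.

Surface extraction emits the voxel boundary faces — the 0.5 level set of
the binary field under nearest-neighbour interpolation. This keeps exact
contracts (enclosed volume = voxel count x voxel volume; watertight without
border contact) that a marching-cubes surface would only approximate.
Binary-field Gaussian smoothing (re-threshold at 0.5) is provided but off
for screw-bearing masks: a structure about one voxel across erodes or
vanishes under a 1.5-voxel kernel, which is exactly why the screws are left
unsmoothed.

Rigid CAD alignment is an explicit configured transform (reproducibility
over interactivity); optional point-to-surface ICP refinement never
increases the mean closest-point distance. Surface deviation samples the
reference vertices and measures unsigned exact point-to-triangle distances
(k-d-tree pruned, verified against a brute-force scan); the summary reports
max, mean and the fraction below 1 mm. The deviation is unsigned because no
sign convention is defined for the comparison it mirrors.

## Material mapping

Bone follows the published two-regime mapping, implemented exactly as
printed: calibrated HU maps piecewise-linearly to apparent density
(trabecular HU [-1000, 500] -> rho [0, 1000] kg/m^3; cortical HU
[501, 1500] -> rho [1001, 2000]) and the regime's power law gives the
modulus, E = 0.0004 rho^2.01 (trabecular, rho < 1000) or
E = 0.005 rho^2.01 (cortical, rho >= 1000) in MPa. The printed intervals
leave a one-unit gap (HU 500 -> 501) that is bridged linearly, and the two
laws disagree at the regime boundary; the discontinuity is reproduced, not
smoothed — fidelity to the published table over physical plausibility. The
table's printed modulus *ranges* (180–380 and 11,300–22,900 MPa) are
inconsistent with evaluating the printed laws at the printed density
endpoints; the laws are authoritative here and the ranges ship as metadata
only. Outside the table, bone-mask HU clamps to the nearest density
endpoint, and a modulus floor of 0.01 MPa keeps stiffness matrices positive
definite where the law evaluates to ~0. Teeth split at 2000 HU into dentin
(E = 24,535 MPa) and enamel (39,605 MPa), both with nu = 0.3; prosthesis
and screws carry Ti-6Al-4V (113,800 MPa, 0.342); the simplified merged-bone
variant uses a uniform 10,000 MPa / 0.3.

Element values sample the HU field trilinearly at the element's four
quadrature points and average (matching where stiffness is integrated; a
centroid-sample alternative is available). The material table ships as a
versioned JSON asset.

## Meshing

Each labelled voxel splits into 6 tetrahedra (the Kuhn split along the main
diagonal, translation-consistent so neighbouring voxels conform without
parity bookkeeping; a 5-tet split would need orientation alternation), then
elements are promoted to 10-node quadratic tetrahedra by inserting exact
edge midpoints. With straight edges the geometry map stays affine, the
4-point Gauss rule integrates the stiffness exactly, and the element volume
decomposition is exact. Nodes deduplicate by exact integer lattice
coordinates at double resolution (corners even, midpoints odd), avoiding
floating-point hashing; part interfaces therefore share nodes (conforming).

The vendor "coarseness" control is replaced by an integer grid downsample
with priority-weighted block voting (metal parts weighted 6x, teeth 2x) so
screw-scale structures survive coarsening; no attempt is made to
reverse-engineer the vendor scale. Jagged voxel surfaces are deliberately
not smoothed before meshing: they are part of what distinguishes a
segmented geometry from its CAD counterpart.

Writers: a subset Abaqus dialect (`*NODE`, `*ELEMENT TYPE=C3D10`, `*NSET`,
`*ELSET`, `*SOLID SECTION`, `*ELASTIC`) with per-element moduli quantized
into at most 100 equal-width bins (error bounded by half a bin width), and
legacy ASCII VTK unstructured grids carrying exact unbinned cell fields.
Both are bit-stable for fixed inputs and the .inp writer round-trips
through the package's own reader.

## Solver

Small-strain isotropic elasticity in fixed mm–N–MPa units. Element
stiffnesses are integrated with the 4-point rule (degree-2 exact; with
constant Jacobians the quadratic displacement field is integrated exactly,
so the patch test passes to round-off). Dirichlet conditions eliminate
dofs with optional prescribed values; reactions are recovered from the full
stiffness. Bonded multi-point constraints interpolate each slave node on
its master facet with the quadratic (T6) facet shape functions, so a slave
coincident with any master node — the case produced by splitting a
conforming interface — is tied exactly; conforming interfaces need no
equations at all. Direct sparse factorization (SuperLU) is the default,
with a Jacobi-preconditioned conjugate-gradient fallback above a
configurable dof threshold.

Contact is node-to-surface with a penalty normal law — a robust desk-scale
surrogate for the "hard contact" of commercial codes, and simpler than the
surface-to-surface variant it approximates. Slave nodes project onto
master facets in the reference configuration (small-sliding assumption).
Per-node normal stiffness is `penalty_scale * E_max * A_trib / h` (default
scale 50, tributary facet area, mean element edge h), escalated 10x
whenever converged penetration exceeds the tolerance of 1e-3 h. Coulomb
friction uses a tangential penalty (0.1 k_n) with radial return: sliding
nodes keep the tangential spring and receive an equal-and-opposite force
pair that caps the net tangential force at mu |N|, preserving global
equilibrium exactly. The solve iterates two levels: an outer active-set /
stick-slip update (with a 5% hysteresis band against chatter) that
refactorizes, and an inner Aitken-accelerated fixed point on the slip
forces that reuses the factorization. Non-convergence raises with the last
state rather than returning silently. On quadratic facets the consistent
normal force routes through midside nodes, so corner slave nodes can report
"slip" while carrying no load; assertions about sticking therefore check
relative slip displacement, not the per-node state.

## Load cases and the variant harness

Required node sets for a solve: prosthesis-condyle fixation, contralateral
condyle fixation, a bite-force region on the first molar, and one region
per muscle attachment, all defined by world-coordinate sphere/box
predicates with part filters. The bite force (450 N default) acts along
the volume's superior axis by default (an occlusal-normal surrogate; the
direction is configurable because no vector is published). Muscle forces
come from a table (name, attachment centroid, force vector in N) applied
unaltered as concentrated loads over their attachment sets; a muscle whose
attachment region resolves to an empty set — because the bone it attaches
to was resected — is dropped, mirroring surgical reality. The phantom's
shipped muscle table is an explicit placeholder with plausible magnitudes
for a 450 N unilateral bite (masseter 150 N, temporalis 100 N, medial
pterygoid 80 N per side, superiorly directed); users substitute their own
musculoskeletal results.

The four variants: Model 1 (fully segmented, HU-mapped bone, no dummy
screws), Model 2 (CAD prosthesis), Model 3 (CAD + dummy screws), Model 4
(CAD + dummy screws, mandible and teeth merged at uniform 10 GPa, coarser
mesh, contact configurable). The industrial-style run is Model 4 with
bonded screw couplings and the plate–bone contact left out — the frozen
reference — and its peak normalizes every variant (the stand-in for a
proprietary material limit; any user-supplied reference is accepted).
`run_all` therefore performs five solves; the Model-4-without-contact
summary reuses the industrial-style computation, since they are the same
model by construction.

In every variant the prosthesis–mandible interface is split into separate
bodies connected only through the bonded screws, so "contact ignored"
genuinely allows separation, "bonded" ties the split pair back, and
"frictional" activates the penalty contact with mu = 0.3. Peaks are taken
at quadrature points, not nodal extrapolations, because extrapolated maxima
grow mesh-dependently.

Problem sizes: the default study runs Models 1–3 at a grid-downsample
factor of 4 (about 15,000 nodes / 45,000 dof each) and Model 4 at factor 8
(about 2,500 nodes), sizes at which the five solves plus the contact
iteration finish in a few minutes on one core while the Model-4 node
reduction (about 6x) still mirrors the published simplification. The
default noise level is sigma = 30 HU. Because the phantom has no
partial-volume blur and the thresholds sit five standard deviations from
every tissue value, segmentation recovers the truth exactly even at that
noise level — so the segmented and CAD-based prosthesis geometries
coincide here, and Models 1 and 2 report equal peaks. On real data they
differ (segmentation artifacts roughen the implant surface); reproducing
that effect would require emulating CT partial-volume physics, which is
out of the phantom's scope. All comparative statements the
package asserts about its own output are directional or bounded (contact
does not raise the peak; dummy screws move it by < 2%); peak magnitudes are
reported, never asserted, because they are properties of the (phantom)
geometry.

## Wear and compression bookkeeping

The gravimetric model is W_n = a n + b: net mass loss after n cycles,
soak-corrected (the soak-control *gain* is added; with the loss-positive
sign convention of the series container, W = specimen loss - control
change). Ordinary least squares (centred, so n ~ 10^6 is well-conditioned)
gives the average wear rate a, rescaled to mg per 10^6 cycles, plus
per-500k-cycle secant rates for step plots; the volumetric rate divides by
the bearing density. UHMWPE density is not published for the device; the
default is 0.93 mg/mm^3, configurable and recorded in the result. The
condylar component uses Ti-6Al-4V at 4.43 mg/mm^3. The cyclic-test
kinematics (12 degree rotation, 8.5 mm anterior/posterior and 0.7 mm
medial/lateral translation, 20 N load, 5 x 10^6 cycles, 500k-cycle
readout) are carried as scenario metadata; no tribological model is
simulated. The compression scenario splits a total load 70/30 between the
ipsilateral (treated) and contralateral sides.

The wear-series generator's default study conditions are 10 readouts at
500k cycles, a small soak drift (0.01 mg per 10^6 cycles), gravimetric
noise of 0.02 mg, and running-in intercepts of 0.15 mg (fossa) and 0.02 mg
(condyle); true rates are set so the bearing couple wears at realistic
fossa/condyle volumetric rates (0.624 and 0.0688 mm^3 per 10^6 cycles).

## Numerical choices and limitations

* Mesh downsampling votes with priority weights; ties break toward the
  higher label id. A part thinner than the coarse voxel can still vanish
  if its weighted count loses everywhere.
* Calibration, mapping and meshing are pure functions of their inputs;
  end-to-end determinism under a fixed seed is asserted in the tests, and
  the run manifest (configs, seeds, reference stress) suffices to
  reproduce every reported number.
* The solver is linear (small strain, small sliding): no plasticity, no
  large deformation, no thread-level screw mechanics — the bonded screw
  idealization is adopted deliberately and is valid only away from the
  thread/interface scale.
* Penalty contact admits penetration up to 1e-3 of the mean element edge
  and adds that compliance to the solution; the escalation loop bounds it.
* The phantom cannot reproduce patient-specific findings such as
  peak-location disagreement between workflows driven by coordinate-system
  and boundary-condition mapping differences; the comparison report only
  flags whether peak locations coincide within a configurable radius.
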