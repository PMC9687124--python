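# Methods

`palpsim` is a desk-scale pipeline for predicting the stress a clinician's
fingers induce on the edge of the liver during abdominal palpation: an
explicit finite-element model of a synthetic abdomen is palpated over a
grid of locations, the resulting maximum-principal-stress fields on the
liver edge form a training set, and a multilayer perceptron learns the map
from (palpation position, contact force) to the stress field so that it
can be evaluated in real time.

## Synthetic abdomen phantom

The phantom is a rectangular block of lumped abdominal tissue ("flesh")
with an embedded ellipsoidal liver and parallel cylindrical rib bars,
voxel-meshed into hexahedra (one element per voxel, part decided by the
voxel-centre predicate).  Default geometry: 96 x 72 x 60 mm block, 6 mm
voxels (1,920 elements), liver ellipsoid centred at (48, 30, 42) mm with
semi-axes (30, 16, 11) mm, three rib bars of 4 mm radius running along x
at 8 mm depth over the liver's superior edge.  The x–y plane is the skin;
z is depth; the base z = 0 is fixed.

This parametric phantom emulates the gross anatomy relevant to
palpation — a palpable organ edge under a soft tissue bulk, partly
shielded by ribs — with explicit, testable geometry.  It does **not**
emulate patient-specific anatomy, organ suspension ligaments, breathing
motion, or the irregular liver outline of a CT-derived model, so passing
tests demonstrate correctness of the pipeline mechanics, not clinical
fidelity of any particular stress value.

Voxel meshing leaves staircase surfaces in general; a Taubin lambda/mu
pass (0.5/-0.53) over boundary nodes smooths them while conserving volume
to well under 1%, guarded by a positive-Jacobian check.

The region of interest is the palpable anterior-inferior liver edge: we
take the liver-surface facets on the inferior (-y) half, bin them by
plan-view angle about the liver centroid, keep the outermost facet per
bin as the discrete "edge curve", and select the liver elements whose
surface-facet centroids lie within a configurable band (default 12 mm,
giving 44 elements on the default phantom) of that curve.  The band rule
is a geometric stand-in: the anatomical criterion that defines a liver
edge on a segmented model is not reducible to a single formula.

## Tissue models (mm–kg–ms unit system; stress in GPa, force in kN)

* **Liver** — visco-hyperelastic.  Equilibrium response: Ogden energy in
  principal stretches, `Psi = sum_p (mu_p/alpha_p)(l1^a_p + l2^a_p +
  l3^a_p - 3)`, evaluated on isochoric stretches, with the fitted pairs
  (8.914e-8, 1.0000), (9.965e-9, 19.0656), (-9.275e-8, -10.9604) GPa.
  The third pair is negative; the ground-state modulus
  `mu0 = sum mu_p alpha_p / 2 = 0.648 kPa` is positive, which we validate
  at construction.  Rate dependence: a Prony shear-relaxation series
  G(t) = sum G_i exp(-t/tau_i) with (6.9701e-6, 10), (5.8327e-5, 1e2),
  (3.5291e-5, 1e3) (GPa, ms).  The decay constants carry no printed unit;
  we read them in the solver's millisecond unit, which places the
  relaxation spectrum across the 25 ms indentation.  The overstress is
  integrated per term with the standard exponential recurrence
  (exact for piecewise-constant strain rate); direct trapezoidal
  quadrature of the convolution integral is kept as a test oracle.
  Volumetric response: quadratic penalty K/2 (J-1)^2 with K derived from
  nu = 0.49 and the *instantaneous* shear modulus mu0 + G(0) (~5 MPa).
  Deriving K from the ground-state mu0 alone would give ~32 kPa, far
  softer than the MPa-scale pressures the surrounding flesh transmits,
  and liver elements would collapse volumetrically; tying the bulk
  stiffness to the instantaneous shear keeps the short-time Poisson
  behaviour near the stated 0.49.

* **Flesh** (lumped abdominal tissue) — nearly incompressible
  neo-Hookean deviatoric stress (G = 4 MPa), volumetric penalty with the
  card's K = 2 GPa, plus a linear viscous stress
  `c * G * dev(D)` with c = 0.4 the card's damping coefficient.  The
  commercial material card behind these constants is not publicly
  specified; we interpret the damping coefficient as a viscous time
  scale in ms so the product is a stress for D in 1/ms.  The same
  coefficient doubles as the mass-proportional damping rate (1/ms) of
  the integrator, which settles the 25 ms ramp into a quasi-static
  response.

* **Ribs** — small-strain von Mises plasticity with linear isotropic
  hardening (radial return).  E = 40 MPa, nu = 0.45, yield 1.8 MPa,
  tangent modulus 1 MPa, hardening modulus H = E Et/(E - Et) =
  1.0256e-3 GPa.

Principal stresses are the ascending eigenvalues of the symmetric Cauchy
tensor; the largest, sigma3, is the quantity visualised on the liver
edge.  Eigenvalue ties are broken by the ascending sort with stable
eigenvector pairing from the symmetric eigensolver.

## Explicit solver

Total-Lagrangian hexahedra with one-point quadrature, central-difference
(leapfrog) time integration, lumped mass.  The fingers are two rigid
hemispherical-capped capsules (default tip radius 8 mm, spacing 20 mm —
the physical platform gives no finger dimensions, so these are package
defaults at human-finger scale) driven down a linear ramp (ramp shape is
unstated upstream; linear is the simplest monotone choice).  Contact is
a frictionless node-to-surface penalty: penetrating boundary nodes are
pushed out along the local capsule normal with stiffness
`0.3 * K_flesh * h` (h = mean element size); the finger reaction is the
negative sum of the nodal forces.

Time step: the Courant bound `h / c` with `c = sqrt((K + 4G/3)/rho)`
(instantaneous moduli for the liver) is corrected for the flesh
viscosity by the standard factor `sqrt(1 + xi^2) - xi`,
`xi = 2 eta / (rho c h)` — without it the viscous stress destabilises
the integration near the pure-CFL limit — and multiplied by a 0.9 safety
factor.  The default phantom runs ~9,700 steps per 25 ms palpation
(~15 s on one CPU).

**Hourglass control and its cost.**  One-point hexahedra need
stabilisation of the four zero-energy modes.  We apply combined
stiffness + viscous Flanagan–Belytschko control with the stiffness
scaled by the *constrained* modulus, `0.01 (K + 4G/3) h` per mode, and
viscosity `0.1 rho c V^{2/3}/4`.  Scaling by the shear modulus alone
(the textbook choice) fails here: the flesh card has K/G ≈ 500, and
concentrated contact loads on a 6 mm mesh drive the unresisted modes
until the contact force collapses.  The chosen default gives a strictly
monotone force history and an energy ledger that closes to machine
precision, but at this deliberately coarse resolution a substantial
fraction of the indentation work is carried by the stabilisation terms;
the ledger reports it honestly in its `hourglass` bucket, and full
2x2x2 quadrature is available (`quadrature="full"`) for verification
runs on small meshes.  Desk-scale force magnitudes (kN at 15 mm
indentation) follow directly from the stiff flesh card and should be
read as model outputs of this phantom, not as human palpation forces.

The energy ledger accumulates finger-side external work, kinetic,
internal, hourglass, mass-damping and contact-spring energies with
mid-step velocities, making the discrete work–energy identity exact up
to the contact bookkeeping; the acceptance suite requires closure within
2%.

**Reduced models.**  `crop_model` keeps elements whose centroids lie in
a box and fixes every newly exposed cut face.  On this small phantom the
choice of cut matters a great deal: fixing *lateral* cut faces confines
the nearly incompressible flesh and stiffens the response by hundreds of
newtons, so the default reduced model for the full-vs-cropped comparison
removes only the bottom 6 mm slab — the boundary farthest (54 mm) from
the indentation site.  Even so the peak-force difference is of order
1e2 N at the ~5 kN force scale of this phantom; a sub-newton agreement
between full and reduced models is only achievable when the cut is many
contact radii away, which requires the element counts of a full-torso
model rather than a desk-scale block.

## Sweep and dataset

The training sweep palpates a 5 x 5 grid over the liver's plan-view
bounding rectangle (x 18–78, y 14–46 mm), 15 mm indentation over 25 ms,
sampling frames at 0, 5, 10, 15, 20, 25 ms: 150 training records.  Three
off-grid locations — (40.5, 26), (55.5, 34), (25.5, 42) — are held out
for testing (18 records).  Each record is (x, y, time stamp, contact
force in N, sigma3 per ROI element in GPa).  Records are written as CSV
with a commented header listing the ROI element ids and units.

## Surrogate

MLP 3 → 64 → 128 → 256 → 512 → ROI size, positive-linear (`max(0, x)`)
hidden activations, linear output.  (The second hidden layer is 128; the
upstream architecture sketch prints "126", which we read as a typo for
the power-of-two convention; the width is configurable.)  Inputs are
min–max normalised to [0, 1] per feature on the training partition;
outputs are standardised by the pooled training mean/std.  Training is
full-batch gradient descent with momentum 0.9 and an adaptive learning
rate (start 0.01, x1.05 after an improving epoch; a step that worsens
the MSE by more than 4% is rejected, the rate x0.7 and the momentum
memory cleared), up to 20,000 epochs with early stop at a normalised MSE
of 1e-5.  Everything is seeded and deterministic.

The goodness of fit is the pooled coefficient of determination in
percent, `100 (1 - sum (y - yhat)^2 / sum (y - ybar)^2)`, pooled over
all held-out records and ROI elements (per-element components are
reported diagnostically).  Pooling over elements and time stamps matches
reporting a single headline number; whether the upstream evaluation
pooled identically is not stated, so the per-element breakdown is kept
available.

## Real-time serving

The physical force plate (400 x 400 mm, one force sensor per corner) is
replaced by a stream of corner-force rows.  The contact position is the
force-weighted centroid of the corner coordinates — the static moment
balance, which the bundled bilinear force splitter inverts exactly — and
totals below 0.5 N mean "no contact".  Predictions are rendered as
plan-view images: each ROI element's voxel footprint is filled with the
colour of its sigma3 under a diverging map (`RdBu_r`, zero at the
neutral colour) clamped to a display range taken from the dataset's
observed extrema; a colour bar is embedded.  Rendering is pure
(byte-identical for identical inputs) and per-frame latency is logged.

## Problem sizes and determinism

Default problem sizes (1,920 elements, 28 simulations, 20,000 training
epochs) are chosen so the full pipeline — sweep, training, evaluation —
completes in roughly a quarter hour on a single CPU while keeping all
three tissue parts, a realistic ROI size, and contact patches several
elements wide.  All randomness (network initialisation) flows from one
integer seed; simulations are deterministic by construction, and
repeated runs are bit-identical.

## Known limitations

* Coarse-mesh hourglass share of the energy budget (above).
* Small-strain rib plasticity is not objective under large rotations;
  rib strains stay small in all palpation scenarios exercised here.
* The flesh "simplified rubber/foam" card is reconstructed as
  neo-Hookean + linear viscosity; the commercial card's load-curve
  behaviour is not public.
* No friction, no self-contact, no tissue relaxation beyond the ramp,
  no respiratory motion, no tumour variants.
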