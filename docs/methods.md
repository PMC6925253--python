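# Methods

`rockbundle` is a desk-scale model of ion-coupled alternating access in a
LeuT-fold-like transporter.  It asks one question: how does an ion bound at a
conserved site on the interface between two helical bundles change (i) the
equilibrium fluctuations of the outward-facing (OF) state and (ii) the
nonequilibrium work needed to drive the OF → IF transition?  Everything is
built so that these comparisons can be computed in minutes on one CPU while
keeping the moving parts of the full workflow — collective variables, steered
dynamics with exact work accounting, completion detection, correlation
networks — as real, tested code.

## The toy transporter

The protein is a ring of 2·H idealized Cα helices (default H = 4 per bundle,
10 residues per helix, bead spacing 1.5, helix radius 1.0, axis spacing 5.0
model units) alternating between two bundles around a pseudo-two-fold z axis.
Bundle 1 is *the moving bundle* by convention; bundle 2 is held fixed in all
reference comparisons.  Loops of 2–3 jittered beads (seeded noise, σ = 0.3)
bridge consecutive helix ends.  The two interface helices (one per bundle)
lean 1.0 unit toward each other: interfaces in real transporters are packed
more tightly than the rest of the ring, and the ion site lives there.

The ion site is found by alternating nearest-bead selection and minimax
(smallest-enclosing-sphere) recentering: two beads of the bundle-1 helix and
three of the bundle-2 helix coordinate a single ion pseudo-particle, all
within a 3.0-unit site radius.  This mirrors the real site's stoichiometry
(two backbone donors on one helix, three oxygens on the other).  Gates are
three-atom groups: the periplasmic gate at the top bead of three ring
helices, the cytoplasmic gate at their bottom beads — mirroring the
three-residue gate definitions used for transition monitoring.

The IF reference is generated by rotating bundle 1 rigidly about the +y axis
through the ring center by the rocking angle (default 25°); loops follow at
half the angle.  Construction fails loudly if the gate radii of gyration do
not shrink (periplasmic) and grow (cytoplasmic) across the OF → IF change,
because completion detection depends on that ordering.

## Energy model

Reduced units: kT ≡ 1, lengths Å-like.  The surface is a double-basin
elastic network combined by exponential (log-sum-exp) mixing,

    V_mix = −(1/β_mix) ln [exp(−β_mix V_OF) + exp(−β_mix V_IF)],

with β_mix = 2.0, plus a soft excluded-volume term and the ion restraints.
Each basin's network connects atom pairs within 10 units of that basin's
reference, with harmonic springs zero at the reference.  Spring constants
encode the rocking-bundle premise:

- intra-bundle pairs: flat k = 10 — the bundles are nearly rigid bodies;
- inter-bundle pairs: native contacts only (reference distance ≤ 4.5), with
  a Gaussian distance decay exp(−(r² − 1.5²)/σ²), σ = 1.5 — the interface
  coupling concentrates at the tight ion-site contact;
- loop pairs: the same decay damped by 0.3 — loops are flexible linkers.

These three choices were the decisive modelling step.  With uniform springs
the inter-bundle barrier is spread over the whole ring surface and no
small set of collective variables can drive the transition: biasing the site
helices just deforms them locally.  With rigid bundles and interface-
concentrated coupling, the site helices become true mechanical handles on
the rocking mode, which is what the underlying rigid-body picture asserts.

The excluded volume is a soft quadratic repulsion below 1.0 unit; pairs
closer than that in either reference are exempted so both references remain
exact stationary points.  All terms depend only on interparticle distances,
so the model energy is invariant under global rigid motion.

The ion term is five harmonic distance restraints (k_ion = 200 in reduced
energy/length², echoing the published 200 kcal/mol/Å² as a label, not a
physical claim) between the ion particle and the site atoms, rest lengths
measured in the OF reference.  Two styles exist:

- `harmonic` (default): permanent restraints — the analogue of the
  restrained-ion equilibrium simulation; used for all equilibrium runs.
- `breakable`: harmonic core out to a displacement cap, then a smooth taper
  to a flat plateau (finite bond depth k_ion·cap²) — a coordination bond
  that can rupture.  Steered runs use this style with cap 0.25 (depth
  ≈ 12.5 kT per restraint): a driven transition must break the site, it
  does not have to fight an unbreakable spring.  The harmonic regime is
  untouched below the cap, so small-displacement arithmetic is identical in
  both styles.

## Dynamics

Overdamped (first-order Euler–Maruyama) Langevin dynamics, Δt = 0.002,
friction 1, temperature kT = 0.5.  First-order dynamics is appropriate for a
Cα bead model and makes the work bookkeeping integrator-agnostic.  Δt was
fixed with a stability ladder (`auto_timestep`: largest candidate step whose
probe run does not diverge); the ion restraints (k = 200) are the stiffest
term and set the bound.

Steered runs add a time-dependent harmonic bias on a CV set with centers
moving linearly from the OF values to the IF values, then held fixed for a
relaxation phase.  Work is accumulated with the force-free identity
ΔW = U(x, c_{t+1}) − U(x, c_t) at each center update — exact for stepwise
schedules, zero for static schedules and during the hold, and reproducible
post hoc from a stride-1 trajectory.

Driven runs also carry a static scaffold: every bundle-2 atom is tethered
(k = 20) to its reference position, and a half-harmonic radial wall (k = 5)
sits one unit outside the reference envelope.  This stands in for the
membrane and the experimental convention that the transition is measured
relative to a fixed bundle: without it the bias is satisfied by rotating or
translating the whole protein.  Bundle 2 is identical in both references, so
the tethers are neutral with respect to the transition itself, and both
terms are time-independent, so they perform no work.  Equilibrium runs are
unrestrained; their analyses superpose on bundle 2 instead.

## Collective variables

- centroid distances (`com_distance`), radii of gyration, RMSD with optional
  Kabsch superposition on a fit group (proper rotations only);
- orientation quaternions by Horn's 4×4 key-matrix eigenproblem, reported as
  the rotation angle 2·arccos|w| in degrees, canonicalized to w ≥ 0, with an
  analytic gradient from first-order eigenvector perturbation (validated
  against finite differences; RMSD steering falls back to central
  differences with step 1e−5);
- a translational `com_projection` CV (centroid displacement along a fixed
  axis).  This extends the core catalogue because the dragged-trap
  validation of the work machinery needs a coordinate whose trap free energy
  is center-independent; a radial distance CV in 3D has a −2kT·ln c entropic
  term and would make the "ΔF = 0" check false.

"Center of mass" means uniform-weight centroid throughout: the beads carry
no masses.

Segment orientations split a helix into extracellular/intracellular halves
(even split by z, extra bead to the extracellular half).  Orientation CVs in
steering protocols are measured **against the IF reference** and driven to
zero.  Driving an angle magnitude *away* from a reference constrains only
the magnitude and leaves the rotation axis free — a bias satisfiable by
rotations about the wrong axis; driving the angle *to* zero against the
target reference pins the full orientation.

## Steering protocols

- `d` — two group-centroid distances: the separation of the two halves of
  the ion site (2 beads vs 3 beads), and the distance between four-bead
  mid-segments of the two site helices.  Group centroids, not single-atom
  pairs: a stiff bias on one bead rips it out of the helix instead of
  steering the bundle.
- `theta` — four segment-orientation angles (both halves of both site
  helices) against the IF reference.
- `dtheta` — the union; the flagship protocol.
- `rmsd` — RMSD of the two site helices to the IF reference, fit on
  bundle 2 (available for protocol-catalogue experiments).

Defaults: 16 000 steering steps + 12 000 hold steps, k_d = 35, k_θ = 3
(energy per unit² / per degree²).  The force constants were calibrated once
on the default model — strong enough that the combined protocol completes
in every replica, weak enough that helices stay intact (the bias force per
bead stays well below the intra-helix spring forces).  The same constants
are used for every condition being compared; seeds are paired between the
bound and apo arms for variance reduction.

Completion is decided from the gate radii of gyration averaged over the hold
(or the last 10% of frames): "complete" requires both gates within 10% of
their IF-reference values *and* the correct opening pattern relative to OF;
exactly one gate satisfying its criterion gives "partial".

On the default model the combined d+θ protocol completes in all replicas in
both conditions; the orientation-only protocol typically ends "partial"
(the angle targets are met while the translation of the moving bundle — and
with it the gate geometry — lags), and the distance-only protocol ends
"none".  Protocol ranking keeps only protocols completing in every replica,
sorted by mean work; mechanistic relevance is reported as metadata, never
scored.

## Analyses

- Correlation networks: frames are superposed on bundle 2 (so rocking does
  not contaminate fluctuations), displacements taken from the mean
  structure, and C_ij normalized to [−1, 1].  Contacts require a pair within
  8.0 units in ≥ 75% of frames.  Edge weights are −ln|C_ij| (absolute value:
  anti-correlated contacts also communicate).  Shortest paths are
  deterministic, ties broken by lexicographic node order.  The inter-bundle
  coupling score is the mean |C| over contact edges joining the two site
  helices across the interface.
- Bundle-relative RMSD: per-frame RMSD of one bundle after fitting on the
  other (or itself); self-fit means never exceed other-fit means.
- Ensemble summaries: per-CV series, means, standard deviations, deviations
  from reference values, and Freedman–Diaconis histograms normalized to unit
  mass (single bin for constant series).

## Pipeline and statistics

`run_pipeline` executes build → bound/apo equilibrium → analyses → steered
suite (10 seed-paired d+θ replicas per condition plus 4 orientation-only
controls) → report.  Each equilibrium arm is four seed-paired replicas of
60 000 steps at Δt = 0.001 whose per-run statistics (distance variance,
bundle-relative RMSD, reference deviations, coupling scores) are averaged:
the mean-based contrasts are dominated by slow collective excursions, and
several independent runs average them far more efficiently than one long
one.  In the bound equilibrium arm the ion is integrated without thermal
noise — its fast solvent-slaved fluctuations are adiabatically eliminated,
so it follows the site deterministically and transmits coupling without
acting as an extra noise source.  (With a thermally agitated single-bead
ion, the five radial-only restraints rectify the ion's noise into a net
outward force on the site, which *destabilizes* the bound state — an
artifact of the one-particle ion representation, not of the physics being
modelled.)  Steered runs keep the fully mobile, thermalized ion.  The work comparison uses a one-sided
paired Wilcoxon signed-rank test (significance 0.05): the underlying claim
is "reproducibly lower in apo", and pairing by seed makes it assertable with
few replicas.  Every verdict in the report is traceable to a numeric row of
the same report, and identical configs with identical seeds reproduce the
report bit for bit.

Problem sizes (equilibrium length, replica counts, steering duration) are
chosen so a full study runs in roughly ten minutes on one CPU; they are the
package's default study conditions, not tuned per machine.

## What the generator does and does not emulate

The synthetic model reproduces the *statistical skeleton* of the real
problem: two quasi-rigid bundles with a soft rocking mode, an interface ion
site whose restraints stiffen exactly that mode, gates whose compaction
tracks the transition, and work measurements dominated by interface rupture.
It does not contain side chains, solvent, membrane, electrostatics, real
sequence, or absolute energetics: passing tests demonstrate that the
*methodology* (CV design, work accounting, network analysis, comparative
statistics) behaves correctly and that the qualitative ion-coupling
phenomenology emerges from the stated assumptions — not that any number in
kcal/mol transfers to a real transporter.

## Numerical choices and degenerate inputs

- Orientation CVs refuse groups of fewer than 3 atoms or (near-)collinear
  geometry; at exactly 0° the angle gradient is the zero subgradient.
- Kabsch superposition always returns a proper rotation (det +1), also for
  reflection-related inputs.
- The energy integrator aborts with the frame index when |V| exceeds 1e8 or
  coordinates go non-finite.
- Correlation analysis raises on zero-variance nodes, naming them.
- Perfectly uncorrelated contacts (C = 0) would carry infinite weight and
  are dropped from the graph.
- Bitwise reproducibility: all randomness flows through seeded
  `numpy.random.Generator` instances; analyses are pure functions.

## Known limitations

- The apo ensemble fluctuates more but stays in the OF basin on the default
  timescales; spontaneous OF → IF transitions (or ion unbinding as seen in
  long unbiased simulations of the real system) are out of reach by design.
- Work values are reduced-unit and comparative; no mapping to kcal/mol is
  implied.
- The orientation-only protocol's "partial" verdict depends on the default
  replica count and temperature; with much stronger biases it can complete —
  the catalogue comparison is meaningful at the calibrated constants only.
- The localized work "hump" at site rupture is visible in individual bound
  work profiles but its position varies between replicas; the package
  asserts only the mean-work ordering.
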