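# Methods

## Scope and model

`dnafem` predicts the mechanical ground state of DNA assemblies whose
secondary structure is built from immobile four-way junctions joined by
B-form duplexes.  The model is junction-centric and lattice-free: duplexes
may be joined in arbitrary 3D topologies, including closed rings, tile
ribbons and 3D crystal-like weaves.

### Strand graph and topology extraction

A design is a directed graph: one vertex per nucleotide, edges for the
phosphate–sugar backbone (5'→3') and for Watson–Crick pairing.  Topology
extraction groups basepairs into **duplexes** (maximal stacked runs; a step
where exactly one strand terminates while the other continues is a *nick*,
recorded by 0-based step index counted 5'→3' along the duplex's reference
strand — the strand holding the lowest nucleotide id).  Backbone edges
whose flanking bps lie in different duplexes are junction links; they must
form disjoint 4-cycles over duplex-end bps, giving **four-way junctions**
with arms in backbone-cycle order.  Any other branch motif (three-way,
five-way, junction touching a duplex interior) is rejected with an
unsupported-motif error rather than guessed.

**Isomer assignment.**  Stacked arm pairs are cycle-adjacent (they share a
continuous strand).  Arm axes are unit vectors from the flanking bp centre
to the bp centre k = min(3, length−1) steps into the arm — a multi-step
estimate chosen for robustness to single-bp noise.  Arm 0 stacks with
whichever cyclic neighbour subtends the angle closer to 180°; exact ties
break deterministically (larger dot-product magnitude, then lower arm
index) with a logged warning.  Once set, the isomer is immutable; stacking
isomer inter-conversion is out of scope.

### Elastic elements

Every bp is a node with six DOFs (position in nm, orientation as a proper
rotation; the bp triad's third axis is the helical axis).  Defaults:

| parameter | value | units | role |
|---|---|---|---|
| axial rise | 0.34 | nm/bp | beam rest length |
| helicity | 10.5 | bp/turn | rest twist 34.29°/step |
| stretch modulus | 1100 | pN | axial stiffness EA |
| bend modulus | 230 | pN nm² | EI |
| twist modulus | 460 | pN nm² | GJ |
| nick factor *b* | 1.0 | – | scales EI, GJ at nicks (never EA) |
| junction offset | 0.925 | nm | centre → each helix axis (1.85 nm total) |
| J_twist ground state | 60 (right-handed) | deg | interhelical scissor angle |
| k_rot about e₁, e₂ | 1353 | pN nm/rad | junction bending/rolling stiffness |
| k_twist about e₃ | 135.3 | pN nm/rad | scissor stiffness |
| junction factor *a* | 1.0 | – | scales all three rotational stiffnesses |
| junction translational stiffness | 1.7×10⁴ | pN/nm | centre coupling (see below) |
| temperature | 298 | K | k_BT = 4.11 pN nm |

**Beam element (one per bp step).**  A discrete elastic-rod step: with
relative rotation Θ = log(RᵢᵀRⱼ) de-twisted symmetrically by the rest
twist (so the 34.29° rest twist does not bleed ~3% into the bend strain),
the energy is ½(EI/L₀)(θ₁²+θ₂²) + ½(GJ/L₀)θ₃², plus axial stretch
½(EA/L₀)(t₃−L₀)² and a stiff shear penalty ½k_sh(t₁²+t₂²) on the chord
expressed in the geodesic mid-frame.  The mid-frame ("trapezoidal")
kinematics reproduce the Euler–Bernoulli cantilever compliance to
O(1/4N²) — 0.25% at ten elements — and the closed-ring bending energy
½BL/R² to ~1% at 100 elements.  k_sh defaults to 100·EA/L₀
(the Kirchhoff/Hermitian limit; shear contributes < 0.1% to test-scale
compliances).

**Junction element.**  Each junction contributes two auxiliary *helix
nodes*, one per stacked arm pair, joined to the four flanking bps by
half-step stacking connectors (ideal half B-form step rest pose, bend/twist
stiffness EI,GJ over 0.17 nm).  The junction proper is a single connector
between the two helix nodes whose rest pose is the canonical stacked-X
ground state — helix axes separated 1.85 nm along the junction e₃ (the
common normal / scissor axis), crossing right-handedly at 60°, each helix
node's first axis facing its partner — and whose energy is
½·a·(k₁φ₁² + k₂φ₂² + k₃φ₃²) in the rotation-vector error measured about
the junction axes, plus an isotropic translational spring.  The energy is
exactly zero at the ground state, and a pure scissor deflection δ costs
exactly ½·k_twist·δ² at any δ.  The translational stiffness is not printed
in the sources this model draws on; 1.7×10⁴ pN/nm makes the centre
effectively rigid relative to duplex stretch (EA/L₀ ≈ 3.2×10³ pN/nm)
while keeping the tangent well conditioned, and is config-exposed.
Realizing the junction with auxiliary nodes keeps all element gradients
closed-form (no rotation averaging inside an energy) at the cost of two
extra nodes per junction, which are reported separately from the bp-node
counts.

### Stress-free initialization and end-pairing constraints

The initial FE configuration is *exploded and stress-free*: every junction
is instantiated in its exact ground-state geometry at the pose fitted from
the designed coordinates (position and through-directions of its flanking
bps), its arms regenerated as straight B-form helices carrying the half of
each connecting duplex nearer to it.  One end-pairing constraint per
duplex-connectivity entry then welds the two facing bps: a 6-DOF connector
whose rest pose is the ideal B-form step, ramped geometrically from 10⁻³
to 1× the nominal step stiffness over 20 load steps and then stiffened
1000× so the residual pose gap falls below 10⁻³ nm and 10⁻³ rad.  The
split point avoids nick steps, so reduced nick moduli survive welding.
Duplexes not attached to any junction (plain duplexes, isolated closed
circles) keep their drawn coordinates.  An `as_drawn` build mode skips the
explosion for designs whose drawing is already topologically continuous
with consistent helical roll.

Penalty welds were chosen over Lagrange multipliers to keep the tangent
positive definite under ramping.  Loop closures can alternatively use an
axis-alignment weld that leaves roll free (`close_loop(..., free_twist=True)`),
the analogue of a torsionally released nick; this is the configuration in
which the closed-loop analytic oracle (radius L/2π, bending energy ½BL/R²)
applies.

### Equilibrium solve

Damped Newton per load step: analytic generalized forces (verified against
central finite differences to 10⁻⁶ relative), sparse tangent assembled
from central finite differences of the *element* gradients (24 batched
evaluations per element type), Cholesky-capable LU with Levenberg
regularization when the tangent is indefinite, per-node step caps
(0.75 nm / 0.5 rad) and an Armijo backtracking line search, so the energy
decreases monotonically within each accepted step.  One node's frame is
anchored during the solve to remove the six-dimensional null space and
released for reporting.  Intermediate ramp stages run at most 20 iterations
(they only warm-start the next stage); the final stage iterates to
per-DOF residuals below 10⁻⁴ pN and 10⁻⁴ pN nm.  Everything is
deterministic: identical models and schedules reproduce iteration counts
and frames bitwise.

Closed-loop twist: a nick-free closed duplex carries the quantized linking
number of its drawn configuration (nearest integer to n/10.5 turns); the
residual register twist distributes uniformly, the minimum-energy
arrangement for homogeneous GJ.

### Normal modes and thermal fluctuations

The tangent stiffness at equilibrium (constraints at their final welded
stiffness) is diagonalized — densely below ~1900 DOFs, otherwise by
shift-invert Lanczos for the lowest modes (default 100).  Rigid-body modes
are identified by eigenvalue magnitude below 10⁻⁸ of the spectral scale;
an unconstrained converged model has exactly six.  Equipartition over the
non-rigid subspace gives the positional covariance k_BT·K⁺ and per-bp
RMSF.  Truncation to the lowest modes biases RMSF low by the 1/λ tail,
which is negligible for the soft-mode-dominated structures here; small
systems use the full spectrum.  Because the eigenproblem weighs every DOF
equally, comparisons with classical beam spectra carry the standard
Rayleigh rotary-inertia correction (≈4% for the first free–free bending
mode of a 100-bp duplex).

### Atomic model generation

Reference atomic structures for the four Watson–Crick bps are assembled at
run time from the ideal nucleotide geometries in biotite's bundled
chemical component dictionary: each base is posed in an idealized pairing
frame (C1'–C1' 10.44 Å, glycosidic bond at λ = 54.5° to the C1'–C1' line,
pseudo-dyad along the frame x-axis), the complementary base generated by
the dyad flip, and the CCD sugar/phosphate carried along rigidly.  Each
bp's reference atoms are rigidly placed at its equilibrium node frame;
chains follow strands (1-based residue numbering 5'→3', deterministic
label rollover past 62 strands).  At every junction, the phosphate and
sugar atoms of the crossing-strand nucleotides at the branch points are
rotated 45° about the C1'→N1 axis (N9 for purines — N1 is not the
glycosidic nitrogen of a purine; both the substitution and the rotation
sign are config-exposed).  The adjustment is applied exactly once;
re-application is refused.  Output is plain ATOM/TER PDB, occupancy 1.00,
B-factors optionally set to per-bp RMSF in Å.

### Analysis

Rigid superposition is a closed-form SVD (Kabsch) fit with reflections
forbidden; RMSD reports are global and per-nucleotide with
fraction-below-threshold curves.  Ring metrics fit per-layer circles
(layers recovered by walking duplexes through stacked junction arm pairs)
in the global best-fit plane; a *bulge* is a locally maximal radial
excursion above 0.3 nm (≈ visual prominence of one helix diameter) between
consecutive junction anchors.  Ribbon chirality accumulates the dihedral
rotation of per-column junction cross-section vectors about the fitted
centreline; |twist| < 2°/repeat classifies as flat (well below the
≈17°/repeat a single-bp arm change implies), right-handed positive.  The
sensitivity scan re-solves the same topology over a factor grid (a, b) and
reports bp-RMSD against the a=b=1 baseline or the chirality class.

## Synthetic designs

The generator module emulates the studied families: concentric rings of
circumferences 100/150/200/250 bp at 2.5 nm designed spacing with five
crossovers per adjacent layer pair (alternating circulation, so adjacent
layers are antiparallel at crossovers), N×M junction ribbons with arm
lengths n_x, n_y ∈ [20, 22] and sticky-end tile joints modelled as two
nicks (one per strand, two steps apart) at every inter-junction midpoint,
single stacked-X junctions drawn in ground-state geometry, and a
three-axis orthogonal strut weave emulating the tensegrity-triangle motif
topologically (three junctions per cell, collinear struts of adjacent
cells merged into continuous duplexes).  Sequences are a fixed cyclic ACGT
assignment — the mechanics is sequence-independent — and every generated
design passes validation with zero violations.  Real designs can be
substituted through the canonical design dialect or the Tiamat importer.

What the generators do *not* emulate: deposited base sequences, exact
crossover placements of published designs (ring crossovers are evenly
spaced and register is reconciled by the solver), electrostatics-driven
layout choices, and the rhombohedral geometry of the real tensegrity
crystal (the weave is orthogonal; only its topology matches).  Passing
tests therefore validate the mechanical model and pipeline, not base-level
agreement with any deposited structure.

## Scaled problem sizes

Ribbon chirality runs at 6×2 repeats in the tests and acceptance script;
twist per repeat is the size-intrinsic measure and the handedness
classifications are unchanged at 10×4 (twist amplitude decreases with
ribbon width, as expected for a stiffer cross-section).  The concentric
rings run at the full 700-bp four-layer design.  The sensitivity scan uses
a two-layer ring and the 6×2 (22,22) ribbon.  At these sizes the nick
softness shifts the (22,22) twist by ≈3°/repeat without flipping its sign;
the class flip itself is expected only at larger widths or different joint
placements.

## Known limitations

Single ground-state junction geometry (no isomerization, no
sequence/solvent dependence), harmonic J_twist response, no
electrostatics, no excluded volume (helices may pass through each other),
no dynamics or folding kinetics, sequence-independent elastic moduli, and
an idealized (fiber-like) reference bp for atomic output.  Ribbon twist
amplitudes depend on assembly width; only their sign pattern is treated as
a prediction.
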