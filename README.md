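# dnafem

Finite-element prediction of the 3D solution structure, thermal
fluctuations and all-atom models of programmed DNA assemblies built from
immobile four-way (Holliday) junctions interconnected by B-form duplexes.

Structural DNA nanotechnology programs megadalton-scale objects — rings,
tile ribbons, 3D crystals — by prescribing Watson–Crick secondary structure.
`dnafem` answers the question those designs leave open: *what 3D shape does
the assembly actually adopt in solution?*  It parses a nucleotide-level
design into a strand graph, identifies duplexes and stacked-X four-way
junctions, builds a coarse-grained mechanical model (one 6-DOF node per
basepair), and solves for the minimum-energy configuration that makes every
designed duplex continuous.  Normal-mode analysis then yields thermal
fluctuations, and standard reference basepairs placed at the equilibrium
frames produce an all-atom PDB model.

## Model

* **Duplexes** — worm-like-chain elastic beams, one element per bp step:
  rise 0.34 nm, right-handed twist 360°/10.5 = 34.29° per step, stretch
  modulus 1100 pN, bend modulus 230 pN nm², twist modulus 460 pN nm².
  Nicked steps optionally scale bend/twist by a factor *b*.
* **Four-way junctions** — immobile stacked-X ground state: the two
  coaxially stacked helix pairs are separated by 1.85 nm along the common
  normal and cross at a right-handed interhelical angle J_twist = 60°.
  Harmonic rotational springs of 1353, 1353 and 135.3 pN nm rad⁻¹ act about
  the junction frame axes **e**₁, **e**₂ and **e**₃ (the scissor axis);
  a factor *a* scales all three.  The isomeric state (which arm pairs
  stack) is assigned once from the designed coordinates and is immutable.
* **Assembly** — each junction starts in its exact ground-state geometry at
  its designed pose with straight B-form arms; ramped end-pairing
  constraints pull topologically continuous duplex ends together until
  they coincide in position and orientation (< 10⁻³ nm / 10⁻³ rad).
  A damped Newton method with analytic gradients and sparse
  finite-difference tangents minimizes the total elastic energy at each
  load step.
* **Fluctuations** — eigenpairs of the tangent stiffness at equilibrium;
  equipartition over the non-rigid modes gives per-bp RMSF at temperature T.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

Generate the four-layer concentric-ring design (circumferences 100, 150,
200 and 250 bp, five crossovers per adjacent layer pair), solve it, and
measure its shape:

```sh
dnafem fixture rings ring4.design
dnafem metrics ring4.design
```

which prints (numbers from this package's solver):

```
layer 100 bp: diameter 10.93 nm, bulges 0
layer 150 bp: diameter 15.38 nm, bulges 6
layer 200 bp: diameter 17.77 nm, bulges 6
layer 250 bp: diameter 19.66 nm, bulges 5
out-of-plane extent 3.61 nm (in-plane 21.30 nm, planar=True)
```

The equilibrium structure stays planar; the inner layer relaxes to its
natural circle (L/π ≈ 10.8 nm) while the outer two layers — whose designed
2.5 nm interlayer spacing exceeds the 1.85 nm junction separation — absorb
their excess contour length in five bulges between neighbouring junctions.

The full pipeline (equilibrium frames, RMSF table, all-atom PDB with the
45° crossover backbone adjustment, reproducibility manifest):

```sh
dnafem run ring4.design out/
```

Python API:

```python
from dnafem import fixtures, build_topology, build_model, solve_equilibrium

design = fixtures.make_lattice_design(fixtures.LatticeSpec(n_x=22, n_y=22,
                                                           repeats_x=6, repeats_y=2))
topology = build_topology(design)      # duplexes, junctions, isomers
model = build_model(topology, design)  # FE model, stress-free start
solution = solve_equilibrium(model)    # ramped-constraint Newton solve
```

A (22, 22)-bp tile ribbon solved this way twists right-handed by ≈ 11° per
tile repeat; (21, 21) is flat and (20, 20) left-handed.

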