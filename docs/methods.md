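# Methods

## Scope and model

`dendricomplex` analyses host–guest complexation between cationic peptide
dendrimers and fullerene cages. It contains three layers:

1. **Structure builders** — residue-level lysine(-glycine) dendrimer trees,
   idealised C60/C70 cages, and initial placement of the cage outside the
   dendrimer.
2. **A coarse-grained (CG) trajectory generator** — overdamped Langevin
   dynamics of the dendrimer + rigid cage + explicit counterions in
   implicit water, used to produce desk-scale trajectories with the
   statistical signatures of complexation (approach, abrupt binding,
   stable complex).
3. **Analysis operators** — shape descriptors, radial fields, spherical
   Poisson electrostatics and hydrogen-bond counting. These are
   resolution-agnostic: they run equally on CG output and on imported
   all-atom coordinate files (PDB/GRO/XYZ; XTC/DCD through MDAnalysis).

Units everywhere: nm, ps, g/mol, elementary charge, kJ/mol; potentials are
reported in mV.

## Dendrimer topology

A generation-*g* lysine dendrimer is one neutral core residue (alanine-like
mass by default, configurable) carrying a complete binary tree of lysines:
a root lysine plus *g* + 1 doubling levels, hence 2^(g+2) − 1 scaffold
lysines, 2^(g+1) terminal lysines and 2^(g+2) − 2 lysine–lysine edges. Each
terminal lysine keeps both its α- and ε-amine protonated at normal pH, so
the bare charge equals the number of terminal NH3+ groups:
Q_bare = N_end = 2^(g+2) (16 for G2, 32 for G3). Glycine spacers, when
requested, are inserted in series on **every** lysine–lysine edge and never
on the core-attachment edge; two glycines per edge on the G2 scaffold give
the 28-insertion, 44-residue double-glycine dendrimer. This construction
reproduces the published residue/charge bookkeeping of all three canonical
dendrimers exactly.

The molecular mass uses condensation-polymer accounting (residue masses
minus one water per amide bond plus one proton per protonated amine). It is
reported for information only: the exact core moiety and protonation
accounting behind published mass figures is not recoverable from counts
alone, so no numerical agreement is claimed or tested.

## Geometry

C60 is the truncated icosahedron (vertex-transitive, three neighbours per
vertex) scaled to a 0.71 nm carbon-centre diameter. C70 is an idealised
D5h construction: the C60 hemispheres about a five-fold axis pushed apart
by one bond length with a 10-carbon equatorial belt inserted. Bond-length
alternation is ignored — downstream analysis only needs the rigid hull.

The dendrimer is embedded at one bead per residue by a self-avoiding
branching walk on the tree: children are placed at the bond length
(default 0.5 nm) in random directions, rejecting placements closer than
0.8 × bond length to any non-bonded bead, with a retry/restart budget.
Embeddings are deterministic per seed and synthetic by design — they are
starting points for relaxation, not equilibrium conformations.

`place_guest` translates the cage COM a fixed offset (default 4.5 nm)
along a laboratory axis from the dendrimer COM, refusing placements inside
the host's bounding sphere. Three axes give three independent starting
conformations.

## Coarse-grained dynamics

Forces:

* harmonic bonds (k = 1000 kJ mol⁻¹ nm⁻², r0 = 0.5 nm) along the tree;
* Weeks–Chandler–Andersen excluded volume between all pairs, with per-group
  diameters (dendrimer 0.40, cage carbon 0.25, counterion 0.30 nm,
  arithmetic-mean mixing);
* a Gaussian attraction well U(r) = −ε_hp exp(−(r/σ_hp)²) between cage
  beads and **uncharged** dendrimer beads only (σ_hp = 0.7 nm, default
  ε_hp = 5 kJ/mol ≈ 2 kBT at 300 K). Excluding the charged terminal beads
  mirrors a hydrophobic interior with a solvated cationic corona; the
  smooth well avoids a second steep wall on top of the WCA term;
* screened Coulomb (Yukawa) between charged beads, ε_r = 78.4, Debye
  length 0.8 nm, cut at five Debye lengths.

Integration is position Langevin: dx = F dt/γ + sqrt(2 kBT dt/γ) ξ with
γ_i = m_i × friction (friction 0.5 ps⁻¹, dt = 2 fs; the constructor
rejects dt × friction ≥ 1). The deterministic move is capped at 0.05
nm/step: a bead that thermal noise pushes into the steep WCA wall would
otherwise overshoot by the explicit-Euler step and diverge. The cap only
engages inside the wall and leaves the thermodynamics of the soft degrees
of freedom untouched (the tethered-bead variance test verifies kBT/k to
5% with the cap active).

The fullerene moves as one rigid body — overdamped COM translation plus
rotational update from the net torque (rotational friction
Σ γ_i r_i²), with the orientation matrix re-orthonormalised periodically.
Cage geometry is therefore preserved to machine precision. All pair forces
use the minimum-image convention in a cubic periodic box; emitted
coordinates are unwrapped, so COM/Rg analysis needs no unwrapping step
(`unwrap_cluster` exists for wrapped external input).

Counterions (−1, chloride mass) are placed uniformly at random, at least
0.4 nm from any bead; their count defaults to the dendrimer's bare charge,
making every simulated system neutral.

### Desk-scale study conditions

The generator's published-protocol analogue (offset 4.5 nm, hundreds of
ns) is far beyond desk scale, so tests and the acceptance study run a
scaled problem chosen once: lysine-G2 + C60 in a 5 nm box, initial offset
2.0 nm, 15 000 steps (30 ps) saved every 100 steps, five seeds, with two
matched controls per seed (ε_hp = 0, and dendrimer alone). At these
conditions the attraction range covers the initial gap, so binding is
drift-dominated and completes within the horizon in every seed, while the
ε_hp = 0 control never sustains d < 1.2 nm. What the CG surrogate
reproduces is the *direction* of every published contrast (binding vs.
none, narrower P(Rg), denser core, larger ζ); its absolute numbers are not
comparable to atomistic explicit-solvent values and are not tested against
them.

## Shape analysis

* d(t): mass-weighted COM distance per frame, minimum image.
* Rg: Eq. form sqrt(Σ m_i |r_i − r_COM|² / Σ m_i); verified against a
  pairwise-distance brute-force oracle.
* Gyration tensor: mass-weighted second-moment tensor; its descending
  eigenvalues (λ1, λ2, λ3) are the squared principal radii. The shape
  invariants are I1 = λ1+λ2+λ3 (= Rg²) and I2 = λ1λ2+λ2λ3+λ1λ3, giving
  asphericity α = 1 − 3 I2/I1², which is 0 for spheres and exactly 1 for
  rods. Eigenvalues below 1e-12 × λ1 are flushed to zero so degenerate
  configurations give exact limits; an all-coincident selection is flagged
  degenerate (α undefined).
* P(Rg): normalised histogram of per-frame Rg over a window (default bins
  0.02 nm).
* Complex detection: centred running mean (default 21 frames, truncated
  endpoints) of d(t); formation is the first time the smoothed series
  stays below the threshold for a hold period (default 10% of the
  duration). The recommended threshold is 1.2 × the equilibrated dendrimer
  Rg; analysis windows default to the second half of a trajectory.

## Radial and sectoral fields

ρ(r) bins selected bead masses by distance to a chosen centre-of-mass
(complex COM for density profiles, dendrimer COM for sectoral maps —
both exposed), averages over frames, and divides by the exact shell
volume 4π/3 (r³_{k+1} − r³_k), converting to g/cm³. Default bin width
0.05 nm.

The sectoral map resolves the same mass in (r, θ) where θ is measured from
the unit vector u pointing from the host COM to the guest COM, split into
two azimuthal halves. The azimuthal reference (φ = 0) is the laboratory +z
axis orthogonalised against u, falling back to +x when u ∥ z; any fixed
convention makes the halves well-defined and lets symmetric inputs be
tested for equality. Frames with coincident axis COMs are skipped and
counted in the metadata. Marginalising the map over θ and halves
reproduces the radial mass histogram exactly.

## Electrostatics

q(r) bins bead charges (dendrimer + counterions by default; water
excluded; cage charges contribute if present but default to zero) into
shells around the dendrimer COM. Q(r) is the running sum from r = 0;
Q_max its maximum, ties resolved to the smallest radius.

The spherically symmetric Poisson equation is solved by Gauss's law:
E(r) = Q(r)/(4π ε0 ε_r r²) on the shell-edge grid (E(0) = 0), then
ψ(r) = ψ(R) + ∫_r^R E ds by trapezoid. Boundary conditions: ψ(R) = 0 or
the Coulomb tail ψ(R) = Q(R)/(4π ε0 ε_r R) (default). The dielectric is a
uniform ε_r = 78.4 (water), configurable.

ζ is ψ at an effective surface. No unique slipping-plane convention
exists; the default is the radius of maximal cumulative charge (where
counterion compensation begins), with density-edge and fixed-radius
alternatives. Because published ζ values depend on an unstated convention,
only the *ratio* complex/dendrimer is asserted, not absolute values.

## Hydrogen bonds

Geometric criterion on all-atom frames: donor–acceptor distance ≤ 0.35 nm
(minimum image) and H–D–A angle ≤ 30° (the de facto standard in trajectory
analysis); the D–H…A convention (angle at the hydrogen ≥ 150° by default
cutoffs) is exposed as an alternative. Donors must carry explicit bonded
hydrogens — nothing is inferred. Intramolecular donor–acceptor pairs are
never counted. The CG generator has no explicit water, so hydrogen-bond
analysis applies to imported all-atom frames and constructed fixtures
only.

## Numerical and design choices

* Overdamped (not inertial) integration: the analysis operators only need
  configurational statistics; the positional variance of a tethered bead
  matches kBT/k, which is the relevant equilibrium check.
* NVT, no barostat: pressure coupling is irrelevant to the operators under
  test.
* Determinism: every stochastic routine takes an explicit seed; identical
  inputs give bit-identical trajectories on one platform.
* Divergence guard: |x − box/2| > 100 box lengths aborts with a
  diagnostic.
* Degenerate inputs: empty selections, zero-mass selections, coincident
  COMs, missing hydrogens and out-of-grid ζ surfaces all raise explicit
  errors rather than returning silent zeros.

## Known limitations

* The CG surrogate has implicit water and Yukawa electrostatics; it cannot
  reproduce atomistic energetics, absolute ζ values, hydration structure
  or hydrogen-bond counts, and is validated only for the direction of the
  complexation contrasts.
* Initial dendrimer embeddings are synthetic self-avoiding walks, not
  equilibrated conformations; analyses discard the first half of each
  trajectory to reduce the dependence on them.
* The C70 belt construction is an idealised uniform-edge cage, adequate
  for rigid-hull analysis but not a chemically accurate geometry.
* Printed molecular masses of the canonical dendrimers are not reproduced
  by residue-mass accounting (see topology section); mass output is
  informational.
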