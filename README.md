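# dendricomplex

Analysis toolkit for **host–guest complexation of peptide dendrimers with
fullerenes**, aimed at people studying dendrimer nanocontainers for
hydrophobic drug delivery.

Cationic lysine dendrimers have a hydrophobic interior and a protonated
(NH3+) terminal shell, which lets them encapsulate poorly soluble guests
such as C60/C70 fullerenes. Complexation shows up in simulation
trajectories as an abrupt, then stable, drop of the centre-of-mass
distance d(t) between host and guest, a narrowing of the radius-of-gyration
distribution P(Rg), a denser interior, and a higher ζ potential. This
package provides the complete measurement chain for those observables,
plus the structure builders and a coarse-grained Langevin simulator needed
to generate test trajectories at desk scale.

## What it computes

* **Topology** — residue-level lysine(-glycine) dendrimer trees
  (generation g carries 2^(g+2) terminal NH3+ groups; optional glycine
  spacers on every lysine–lysine edge) with exact residue/charge
  bookkeeping (N_res, N_end, N_ins, Q_bare), and C60/C70 compositions.
* **Geometry** — truncated-icosahedron C60 and belt-inserted C70 cages,
  self-avoiding dendrimer embeddings, initial guest placement.
* **CG dynamics** — overdamped Langevin: harmonic bonds, WCA excluded
  volume, short-range hydrophobic attraction (cage ↔ uncharged dendrimer
  beads), Yukawa electrostatics, rigid-body cage, explicit counterions,
  periodic box.
* **Shape** — d(t); Rg = sqrt(Σ m_i |r_i − r_COM|²/Σ m_i); gyration-tensor
  eigenvalues λ1 ≥ λ2 ≥ λ3 with invariants I1 = Σλ, I2 = λ1λ2+λ2λ3+λ1λ3
  and asphericity α = 1 − 3 I2/I1² (0 = sphere, 1 = rod); P(Rg);
  complex-formation detection.
* **Fields** — radial density ρ(r) = m(r)/V(r) in g/cm³ and the
  two-dimensional sectoral radial mass map (r × polar angle from the
  host→guest axis, split into azimuthal halves).
* **Electrostatics** — radial charge q(r), cumulative charge Q(r) and
  Q_max, numerical spherically symmetric Poisson solution ψ(r), and ζ
  potential under explicit surface conventions.
* **Hydrogen bonds** — geometric donor/acceptor counting (0.35 nm / 30°
  default) on all-atom frames.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from dendricomplex import (build_system, SimParams, simulate, com_distance,
    detect_complexation, rg_series, gyration_summary, electrostatic_profile)

# lysine G2 dendrimer + C60, neutralised with 16 Cl-, 5 nm periodic box,
# guest started 2 nm from the host COM
system = build_system("lysG2", fullerene=60, box=5.0, offset=2.0, axis="x", seed=1)
print(f"system: {system.n_beads} beads, net charge {system.charges.sum():+.0f} e")

params = SimParams(n_steps=15_000, save_every=100, seed=1)   # 30 ps, 2 fs steps
traj = simulate(system, params)

d = com_distance(traj, "dendrimer", "fullerene")
formed = detect_complexation(d, threshold=1.2)
print(f"complex formed at t = {formed} ps; final d = {d.values[-1]:.2f} nm")

sel = traj.select("dendrimer") | traj.select("fullerene")
rg = rg_series(traj, sel)
print(f"complex Rg (second half) = {rg.values[75:].mean():.2f} nm")
gyr = gyration_summary(traj.positions[-1], traj.masses, sel)
print(f"asphericity alpha = {gyr.alpha:.3f}")

es = electrostatic_profile(traj, window=(75, traj.n_frames))
print(f"Q_max = {es.Q_max:.1f} e at r = {es.r_at_Qmax:.2f} nm; zeta = {es.zeta:.1f} mV")
```

Output:

```
system: 92 beads, net charge +0 e
complex formed at t = 0.6 ps; final d = 0.23 nm
complex Rg (second half) = 0.71 nm
asphericity alpha = 0.195
Q_max = 13.1 e at r = 1.25 nm; zeta = 123.7 mV
```

Reading: the guest binds almost immediately at this desk-scale offset and
stays at d ≈ 0.2 nm from the host COM (deep encapsulation); the complex is
compact (Rg ≈ 0.7 nm) and roughly spherical; the cumulative charge peaks at
13 e where counterion compensation begins, and the potential there defines
the ζ estimate. Absolute CG numbers are model-specific — the meaningful
statements are the contrasts against the matched controls (no attraction,
dendrimer alone), which the test suite asserts over five seeds.

A command-line interface wraps the same calls:

```bash
dendricomplex build --preset lys2Gly --out topology.json
dendricomplex simulate --config sim.yaml --seed 1 --out traj/
dendricomplex analyze shape --traj traj/traj_s1.xyz
dendricomplex analyze electrostatics --traj traj/traj_s1.xyz --dielectric 78.4
dendricomplex report --config pipeline.yaml
```

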