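# diabatmd

Excited-state Born–Oppenheimer dynamics with a single-determinant
excited-state SCF (ΔSCF) coupled self-consistently to a polarizable
induced-point-dipole environment, accelerated by Grassmann-manifold
density-matrix extrapolation, with proton-coupled electron-transfer (PCET)
trajectory analysis — all at desk scale.

## Who this is for

Photochemistry of chromophores inside proteins is often gated by
charge-transfer (CT) states: an electron hops between residues, the
environment repolarizes around the new charge distribution, and a proton
follows. Simulating that with linear-response excited-state methods is
expensive and breaks down exactly where it matters (diradical character,
state-specific environment response). `diabatmd` implements the alternative
strategy at a size where every number can be checked against exact
diagonalization: the excited state is one self-consistently optimized
determinant, the environment responds to *that state's* density, and the
dynamics stays on one diabatic surface whose character does not change with
nuclear geometry.

## What is inside

* **ΔSCF excited states.** The excited determinant is built by moving one
  electron from an occupied to a virtual MO and re-optimized with an
  open-shell SCF. Collapse onto the ground state is avoided either by
  maximum-overlap occupation selection against a fixed initial reference
  (iMOM) or by level shifting the complement of the reference occupied
  space so the target state fills by Aufbau (STEP):
  `F' = F + σ (S − S C_ref C_refᵀ S)`. Along MD the previous step's
  converged MOs serve as the reference, so the *same* diabatic state is
  followed through crossings.
* **Polarizable embedding.** Environment sites carry permanent charges,
  dipoles and traceless quadrupoles plus isotropic polarizabilities;
  induced dipoles solve `(α⁻¹ − T) μ = E` with Thole-damped mutual
  induction by preconditioned conjugate gradient. The QM density and the
  induced dipoles are mutually converged inside every Fock build, giving
  the state-specific polarization that makes the CT state's `E_pol`
  strictly lower than the ground state's.
* **Grassmann extrapolation.** Converged spin densities are mapped to the
  tangent space of the Grassmann manifold (`Γ = U arctan(Σ) Vᵀ` from the
  thin SVD of `(I − C₀C₀ᵀ) C (C₀ᵀC)⁻¹`), extrapolated linearly with
  coefficients fitted on the Coulomb-matrix descriptor of the last M=6
  geometries, and mapped back — the guess is idempotent with exact trace
  by construction, for both spins.
* **BOMD.** Velocity Verlet with the Bussi stochastic velocity-rescaling
  thermostat (τ = 0.1 ps, dt = 0.5 fs defaults), analytic Hellmann–Feynman
  forces for the π-electron (PPP) backend including the embedding terms,
  frozen-atom masks, bit-reproducible checkpoints.
* **PCET analysis.** Proton-transfer coordinates (donor–H vs acceptor–H
  distances), persistent transfer-event detection with hysteresis,
  dipole-based LE/CT state assignment, torsion-window conformer labels,
  and ensemble delay statistics.
* **Electronic backends.** A contracted s-type Gaussian integrals provider
  (closed-form Boys-function integrals) and a Pariser–Parr–Pople π-model
  with exponential hopping and Ohno repulsion; a dense full-CI routine over
  the same integral contract is the exact reference used throughout the
  tests.

The headline fixture is a donor–bridge–acceptor PPP toy with a mobile
classical proton and a polarizable shell, built and verified by
`make_pcet_toy`: its CT state pushes the proton from the donor to the
acceptor (electron transfer gates proton transfer), and the vertical LE/CT
ordering flips as the proton moves along its track.

## Worked example

One full photocycle on the seeded toy — ground-state equilibration, sudden
switch to the CT surface, forward proton transfer, back electron transfer,
reverse proton transfer:

```python
from diabatmd import make_pcet_toy, PCETToySpec, run_pcet_cycle

toy = make_pcet_toy(PCETToySpec(seed=1))
res = run_pcet_cycle(toy, seed=11)
print(f"excitation energy : {res.excitation_energy:.4f} hartree")
print(f"GS / CT dipole    : {res.gs_dipole:.2f} / {res.ct_dipole:.2f} e*bohr")
print(f"E_pol GS / CT     : {res.gs_epol*1e3:.3f} / {res.ct_epol*1e3:.3f} mhartree")
print(f"forward PT delay  : {res.forward_delay_fs:.1f} fs after the CT onset")
print(f"reverse PT delay  : {res.reverse_delay_fs:.1f} fs after back-ET")
```

prints

```
excitation energy : 0.5215 hartree
GS / CT dipole    : 3.04 / 8.48 e*bohr
E_pol GS / CT     : -2.630 / -2.789 mhartree
forward PT delay  : 20.0 fs after the CT onset
reverse PT delay  : 5.5 fs after back-ET
```

The dipole nearly triples at the switch (an electron moved ~9.5 bohr from
donor to acceptor), the environment stabilizes the CT state more than the
ground state (state-specific polarization), and the proton transfers within
tens of femtoseconds of reaching the CT surface — then returns once the
electron hops back, closing the cycle.

The same workflow is scriptable from a shell:

```bash
diabat-md make-toy --seed 1 --out run/
diabat-md md --config run/run.toml
diabat-md analyze --traj run/traj.xyz --spec run/run.toml --report run/report.tsv
```

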