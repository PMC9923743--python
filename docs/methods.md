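# Methods

This note records the models, algorithms, defaults and numerical choices
behind `diabatmd`, and what the synthetic systems do and do not probe.
Everything is in Hartree atomic units internally; files use Å and fs.

## Electronic backends

**Gaussian provider.** Contracted s-type Gaussians only, with closed-form
overlap, kinetic, nuclear-attraction and two-electron integrals through the
Boys function F0. This keeps the ab initio path small while exercising the
full SCF/ΔSCF/embedding stack on real integrals (H2, HeH+, H4 with STO-3G
s-contractions). Chemistry realism is delegated to the π-model.

**PPP provider.** One basis function per π site. Hopping decays smoothly
with distance, t(r) = t0·exp(−(r−r0)/λ) (defaults t0 = −0.12 Ha,
r0 = 2.5 bohr, λ = 0.8 bohr), which gives analytic forces. Two-center
repulsion is the Ohno interpolation γ(r) = U/√(1+(U r)²) with
U = (U_i+U_j)/2, finite at contact and →1/r at long range; the on-site
value is the Hubbard U. Atoms without a basis function are bare cores
(e.g. the mobile proton) that interact through the same γ with their own
screening parameter (`bare_core_u`, default 0.5 Ha); using one interaction
law for electrons, cores and bare cores makes neutral fragments field-free
at long range, which the PCET toy's electrostatic gating relies on.

Because the π Hamiltonian has no short-range wall (hopping attraction
grows exponentially as bonds compress), every atom pair additionally
carries a Born–Mayer σ-skeleton repulsion A·exp(−(r−r0)/ρ) (A = 0.08 Ha,
ρ = 0.4 bohr). This gives each bond a genuine minimum (the symmetric dimer
equilibrates near 2.4 bohr) and keeps the bare proton at hydrogen-bond-like
distances instead of fusing with a site.

**Exact reference.** A dense full CI over the same integral contract
(Slater–Condon rules in the Löwdin-orthonormalized basis) provides exact
energies, state characters (via one-particle density matrices and dipoles)
and the variational bounds E_FCI ≤ E_UHF ≤ E_RHF asserted in the tests.
The test suite additionally carries two fully independent oracles — a
loop-based textbook SCF and a spin-orbital bitstring FCI — written against
the definitions, not the package code.

## Ground-state SCF

Restricted/unrestricted Roothaan iterations with Pulay DIIS (error
X·(FDS−SDF)·X in the orthonormal basis, history 8, started at cycle 2).
Convergence requires both max|FDS−SDF| < 1e-8 and |ΔE| < 1e-10 by default
(tighter in the MD drivers). The default guess diagonalizes the core
Hamiltonian; spin-symmetry breaking for diradicals is available through an
α HOMO/LUMO mixing angle.

Near-degenerate configurations (e.g. the closed-shell state after back
electron transfer, where donor-anion and acceptor-anion configurations
cross) make plain DIIS limit-cycle. The solver therefore runs a
convergence ladder: plain DIIS → a heavily damped fixed-point pass
(density mixing 0.7) → with an embedding, macro-iterations that alternate
SCF at frozen induced dipoles with damped dipole updates. The frozen-μ
inner functional Ẽ(D) = E_QM + E_es(D) + ½μᵀAμ − μᵀE(D) is variational in
D and shares its joint fixed point with the fully coupled equations, so
the ladder changes robustness, never the answer. Unconverged results are
returned flagged, never silently.

## ΔSCF excited states

The excited determinant starts from a ground-state orbital promotion
(index-based or by labeled selector: the frontier orbital with > 50%
Löwdin weight on a named atom group, ambiguity window 0.05). Iterations
are always open-shell.

* **iMOM** re-selects, every cycle, the n_σ orbitals with maximal
  projection p_j = ‖C_refᵀ S c_j‖₂ onto the *fixed* initial reference
  occupied space (2-norm metric: invariant to rotations within the
  reference space). Ties within 1e-8 break toward lower orbital energy
  and are logged.
* **STEP** runs in two stages. Stage 1: damped Aufbau iterations on the
  shifted Fock F' = F + σ(S − S C_ref C_refᵀ S) with the *fixed* initial
  reference projector and an automatic shift
  σ = (max ε over reference-occupied − min ε) + margin (margin 1 Ha).
  The fixed projector is essential: an excited determinant is a saddle of
  the SCF functional, and a projector that tracks the current iterate
  slides off it toward the ground state. Stage 2 polishes to stationarity
  of the *unshifted* equations by maximum-overlap selection against the
  stage-1 occupied space. iMOM and STEP agree to ~1e-14 on every fixture.

Collapse is declared when every converged occupied orbital projects > 0.999
onto the ground-state occupied space (the reference ground orbitals are
kept from excitation time along a trajectory). Along MD, the previous
step's converged MOs are the reference and the Grassmann extrapolation the
guess; the reference being slightly inconsistent with the extrapolated
density is harmless because it only selects the state.

ΔSCF solutions can genuinely disappear at some geometries (the embedded
excited stationary point annihilates near strong mixing regions). The MD
driver treats a convergence failure as a halting condition with full
context — failed excited-state segments are a first-class outcome, and the
photocycle workflow ends a CT segment at the last converged frame if the
forward proton transfer has already completed.

## Polarizable environment

Sites carry permanent charge/dipole/traceless-quadrupole moments and
isotropic polarizabilities. Induced dipoles solve (α⁻¹ − T)μ = E_perm by
conjugate gradient with the diagonal (α) preconditioner to residual 1e-10
(1e-8 default outside MD), warm-started between Fock builds; mutual
induction uses Thole exponential charge-smearing damping (a = 0.39,
u = r/(α_iα_j)^(1/6)); site pairs sharing a group id (one group per
"residue analog") are excluded from mutual induction. Frozen far sites
keep their permanent multipoles but have α = 0 and leave the polarization
system entirely. E_pol = −½Σμ·E_perm at the variational optimum.

QM→environment coupling uses Löwdin atomic point charges; the
environment→QM operator is the site-potential × number-operator in PPP
mode, and in Gaussian mode exact charge-type integrals for the monopoles
with dipole/quadrupole/induced potentials applied through the Löwdin
charge operator. The asymmetry is deliberate and documented: the total
energy is defined by the implemented expression, and forces differentiate
exactly it, so the dynamics is strictly consistent even though the
coupling is a desk-scale surrogate for density-level embedding. There are
no cutoffs (direct O(N²) sums) and no damping between QM charges and
induced dipoles — environment shells are kept ≥ ~10 bohr from the QM
region, and there is no exchange wall against the environment, so
structures that push QM atoms onto environment sites are unphysical (the
geometry relaxer clamps its steps to stay in the starting basin for
exactly this reason).

## Grassmann density extrapolation

Idempotent fixed-trace densities live on a Grassmann manifold. With a
fixed per-window reference C₀ (the first density of the window), the log
map is Γ = U·arctan(Σ)·Vᵀ from the thin SVD of (I−C₀C₀ᵀ)C(C₀ᵀC)⁻¹ and the
exp map is C = (C₀V·cosΣ + U·sinΣ)Vᵀ, D = CCᵀ — idempotent with exact
integer trace by construction, never purified. History capacity M = 6.
Coefficients minimize ‖d_now − Σc_k d_k‖² + λ‖c‖² (λ = 1e-10) on the
unsorted upper-triangle Coulomb-matrix descriptor (M_IJ = Z_I Z_J/r_IJ,
M_II = ½Z^2.4; atom order is stable along a trajectory, and sorting would
break smoothness). α and β densities are extrapolated independently with
one shared coefficient vector (a single molecular descriptor describes
one geometry). When the newest density's largest principal angle from C₀
exceeds 1 rad the window resets with that density as the new reference
(tangent vectors must share one base point to be combined linearly).

On the toy's thermostatted ground-state MD, mean SCF iterations per step
are ~4.1 (Grassmann) vs ~6.3 (previous density) vs ~8.0 (core guess) —
the acceleration the scheme exists for, asserted in the tests.

## Dynamics

Velocity Verlet (two half-kicks), dt = 0.5 fs default. Forces on the PPP
surface are analytic Hellmann–Feynman terms: dt/dr and dγ/dr
contributions, the Born–Mayer wall, core–core terms, and q_a·E_env(r_a)
for the electrostatic/polarization coupling (induced dipoles at their
variational optimum need no response terms); they agree with central
finite differences of the fully self-consistent energy to < 1e-6
hartree/bohr on both surfaces. A finite-difference mode with state
tracking at the displaced geometries covers the Gaussian backend. Frozen
atoms have zero velocity and force at all times; environment sites are
static (there is no intra-environment force field in scope — their
frozen/polarizable flags only control the polarization treatment).

The Bussi stochastic velocity-rescaling thermostat uses
α² = c + (1−c)(K̄/(N_f K))(R₁² + χ²_{N_f−1}) + 2R₁√(c(1−c)K̄/(N_f K)),
c = exp(−dt/τ), τ = 0.1 ps default, with the χ² deviate drawn from a
gamma distribution; τ → ∞ returns exactly 1 (NVE). Initial velocities are
a seeded Maxwell–Boltzmann draw with frozen atoms zeroed and the
moving-atom COM motion removed; nuclei are classical throughout (no
zero-point energy). N_f = 3 × (moving atoms).

Checkpoints store geometry, velocities, densities, occupied orbitals, the
extrapolation window, the last induced dipoles and the explicit RNG state
in one `.npz` container; a restarted run repeats the identical arithmetic
(the force evaluation always re-solves the polarization warm-started from
the stored dipoles), so trajectories are bit-reproducible across the
restart. Every emitted byte is a function of (seed, config, inputs).

NVE validation runs from the locally relaxed toy at a 50 K draw: the
total-energy deviation over 2000 steps at dt = 0.5 fs stays below 1e-5
hartree (measured ~1e-6) with no secular trend. The deviation scales as
(ω dt)² per mode, so hot starts on the stiff proton mode would trade
integration accuracy for nothing physical.

## The PCET toy

Five π sites (donor pair, one bridge, acceptor pair) on a line, 2.5 bohr
intra-fragment spacing and 3.5 bohr fragment gaps, plus a mobile bare
proton whose track runs parallel to the chain between two anchors 2.4 bohr
off-axis. Site energies: donor −0.30 Ha (deep: the donor holds four
electrons, its antibonding combination is the HOMO, like a high-lying π
lone pair), bridge +1.0 Ha (an empty superexchange relay), acceptor at a
bias calibrated at generation time. Core charges 1.5/1.5/0/1/1 and six
electrons make donor+proton, bridge and acceptor separately neutral in the
dark state. The CT excitation promotes the donor-localized HOMO electron
into the acceptor-localized LUMO: donor +1, acceptor −1, and the proton —
adjacent to the now-positive donor — is driven toward the acceptor:
electron transfer gates proton transfer. After the transfer the
closed-shell state is a donor anion next to a protonated-acceptor cation,
so back electron transfer (a fresh closed-shell Aufbau SCF from the core
guess, no reference tracking) drives the reverse proton transfer.

The acceptor-site energy bias is chosen by a generation-time scan (not a
hand number): for each candidate bias the FCI LE/CT vertical ordering is
computed along the proton track (states classified by their dipole shift
along the donor–acceptor axis), and the bias whose ordering flip lands
nearest 40% of the track is kept (0.14 Ha, flip at 0.46 for the default
spec). Every delivered toy is verified at build time: (a) ground-state
fragment charges within 0.2 e of neutral, (b) CT dipole ≥ 2× the
ground-state dipole, (c) the CT force on the proton points from the donor
anchor toward the acceptor anchor — a violation raises instead of handing
out a bad fixture.

Two fixture-level restraints are part of the toy's differentiable MD
surface: a transverse harmonic tether of the proton to its track segment
(k = 0.02 Ha/bohr², zero force anywhere on the track) standing in for the
hydrogen-bond chain that confines the proton in a real active site, and
harmonic position tethers of the π sites to their design positions
(k = 0.05 Ha/bohr²) standing in for the scaffold that holds residues in
place. Without them the ~0.1 Ha released by the proton transfer ejects
the light particle from the six-atom system (a real protein absorbs that
energy into thousands of modes) and thermal motion buckles the
unsupported chain.

The environment shell is built from neutral ± charge pairs (one group
each, so intra-pair induction is excluded) at 14–22 bohr with small random
permanent dipoles/quadrupoles and polarizabilities ~6 bohr³; sites beyond
18 bohr are frozen and depolarized. Randomness flows from the single spec
seed.

**What the toy does and does not show.** It reproduces, at six atoms, the
*mechanistic* phenomenology: a diabatic CT state trackable through the
LE/CT crossing, state-specific polarization (E_pol(CT) < E_pol(GS)),
electrostatic gating of proton transfer by electron transfer, and the
forward/backward PCET cycle with femtosecond-scale transfer delays.
Passing tests therefore validate the algorithms, not any real system's
energetics: absolute excitation energies, barrier heights and transfer
times are model numbers (the ~20–70 fs forward delays are the toy's
analog of the tens-of-femtoseconds delays seen in full-scale
simulations); there is no exchange repulsion against the environment, no
quantum proton, and no attempt to parameterize a real flavin site.

## Analysis conventions

A proton-transfer event is a persistent distance-ordering swap: the first
frame where d(donor,H) − d(acceptor,H) > 0.1 Å with the sign holding for
50 consecutive frames (25 fs at the default dt); reverse events swap the
roles, and events alternate by construction. These two thresholds appear
in every report header. LE/CT assignment thresholds the median-filtered
(11-frame) dipole magnitude, calibrated as the midpoint of the fixture's
GS/CT endpoint dipoles; transfer-delay statistics are referenced to the
first CT-like frame. Dihedral labels use the IUPAC signed convention on
half-open windows in [−180°, 180°), with gaps mapping to "other".

## Problem sizes used by the shipped validation

Oracle comparisons run on 2–5-basis-function systems where dense FCI is
exact and instantaneous. The dynamics validation uses the 6-atom toy with
a 24-site shell: 2000-step NVE, 200-step guess-acceleration comparisons,
a 10⁵-step harmonic thermostat check, and photocycles of a few hundred
steps per segment — each segment ends as soon as its transfer event has
persisted, which keeps a full cycle around half a minute while exercising
every component end to end.
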