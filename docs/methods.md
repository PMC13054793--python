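# Methods

This note records the modelling decisions behind `hatforge`: what each
stage computes, the parameters that matter, what the synthetic fixtures
do and do not emulate, and the numerical conventions.

## Units and conventions

Lengths in Å, energies in eV, forces in eV/Å, masses in amu, time in fs;
k_B = 8.617 × 10⁻⁵ eV/K. 1 kcal/mol = 0.04336 eV is a display conversion
only. Atom indices are 0-based everywhere, including serialized metadata.

## Molecule catalog

Peptides are assembled as SMILES from residue fragments
`N[C@@H](R)C(=O)` (glycine and proline special-cased), giving uncapped
chains terminated by free NH2/COOH, or capped chains with an acetyl group
at the N-terminus and an N-methylamide at the C-terminus. Dipeptides are
all ordered pairs of the 20 standard residues (20² = 400 — only ordered
enumeration yields that count). Ionizable side chains (Arg, Lys, Asp,
Glu, His) are built neutral and flagged; no protonation-state enumeration
is attempted. 3D structures come from RDKit ETKDGv3 embedding (exact
reproducibility under a fixed seed) followed by an MMFF94 clean-up.
Per-atom residue annotations, needed by the parent→child trimming, are
derived from fragment atom counts in SMILES order (RDKit preserves it)
with hydrogens inheriting their heavy neighbor's residue.

## Calculators

A calculator is anything with `energy_forces(geometry)`. The built-in
toy potential is the desk-scale labeling engine:

* harmonic bonds (default k = 20 eV/Å²) with equilibrium lengths taken
  from a reference geometry, so the reference is near a minimum of its
  own surface;
* harmonic angles (k = 2 eV/rad²) from the bonded topology;
* Lennard-Jones on pairs that are neither bonded, 1–3, nor reactive
  (ε = 0.003 eV, σ = 1.8 × covalent-radius sum);
* when a reactive triplet (donor, H, acceptor) is declared, the
  donor–H and acceptor–H interactions become Morse wells
  (D_e = 4.0 eV, a = 2.0 Å⁻¹, r_e from the X–H reference-bond table
  below). D_e and a were chosen once so that toy transfer barriers land
  in the 0.5–3 eV range typical of peptide HAT; they are configuration
  constants, not fitted values.

Forces are the exact analytic gradient (verified against central
differences to < 10⁻⁵ eV/Å). The potential has no dihedral terms — see
the sampling note below — and no solvent model; the dielectric setting
(default ε = 10, a protein-like environment) is carried in
`CalculatorSettings` for external-engine adapters only. Adapters for
"xtb" and "turbomole-bmk" are registry entries that raise until an
implementation is installed; a mock adapter in the tests demonstrates
the contract.

Geometric checks used throughout: a clash means a non-bonded pair closer
than 0.7 × the covalent-radius sum (Cordero radii), with a 0.9 Å floor
for pairs involving hydrogen, whose scaled radius sum would be far below
contact distance. A bond counts as intact while its length stays within
20% of the reference value. Both thresholds are configurable; the values
are standard steric conventions, chosen once.

## Normal-mode sampling

The Hessian (central finite differences, default step 10⁻³ Å, symmetrized)
is mass-weighted; rigid translations and rotations are projected out with
an orthonormalized basis (5 rigid modes for linear molecules, detected by
a smallest principal moment below 10⁻³ amu·Å²); the remaining eigenpairs,
sorted ascending, are the vibrational modes. A retained eigenvalue below
−10⁻⁴ triggers a not-a-minimum warning.

Each sample displaces the conformer along all modes at once with
mass-weighted amplitudes d_m = s_m √(3 c_m k_B T / k_m): signs s_m
uniform ±1, fractions c_m i.i.d. uniform and normalized to sum to one per
sample (an "independent" mode is available), so the harmonic energy of a
draw is 3/2 k_B T in total. Default sampling temperature is 500 K —
hot enough to populate a broad band while the 5.0 eV retention bound does
the final gating. Acceptance requires the bond check and a relative
energy within 5.0 eV of the equilibrium conformer; candidates are drawn
until J are accepted or a 20·J retry budget is exhausted.

One sampler-specific parameter deserves emphasis:
`NMSParams.min_force_constant` (default 0.1 eV/Å²·amu) floors k_m in the
displacement formula. The toy potential has no torsional stiffness, so
its softest modes are nearly free; a linearized displacement along such a
mode is arbitrarily large and tears bonds in essentially every draw. The
floor caps those amplitudes while leaving genuine vibrations (k ≫ 0.1)
untouched, and also guards against small negative eigenvalues at
imperfectly converged minima.

Conformer ensembles come from RDKit's multi-conformer ETKDG with MMFF
energies, behind the same `Conformer` type an external ensemble
generator would populate. Selection keeps the 5 lowest-energy plus 5
uniformly random higher-energy conformers (C = 10), returning undersized
pools whole with a warning.

## Radical systems

A radical is created by deleting a hydrogen with exactly one heavy
neighbor; the orphaned heavy atom is the acceptor and the multiplicity
becomes 2. Transfer-eligible hydrogens are those bonded to C, N, O or S;
the rule table is configuration (e.g. drop O to exclude hydroxyls).

Inter-HAT systems pose a donor molecule (uniform random orientation) so
its transferring hydrogen sits at a sampled distance from the radical
site along a uniform random direction. The distance law is a scaled χ²
with df = 3 and scale 2.5 Å — pre-truncation mode at 2.5 Å — truncated by
rejection to [1.2, 4.0] Å; the floor avoids immediate overlap, the cap is
the workflow's stated bound, and all four numbers are configuration.
Poses must be clash-free, and no competing hydrogen may sit closer to the
acceptor than the transferring one. Hydrogens covalently bonded to the
acceptor itself are exempt from that rule: a CH2• center keeps an H at
bond distance, which is part of the radical site, not a transfer
competitor. Intra-HAT systems enumerate (abstracted H, transferring H)
pairs within one molecule under the same distance cap and proximity rule
and pick one uniformly.

The end position r_1 lies at the reference X–H bond length from the
acceptor (C–H 1.09, N–H 1.01, O–H 0.96, S–H 1.34 Å) along the
acceptor→start-H direction. The displacement function places the hydrogen
on a sphere centered at the arithmetic midpoint of start and end, radius
uniform on [0, span/2 + 0.3 Å] — the margin reaches slightly off-path
points — and direction uniform; candidates must pass the clash check and
stay within the energy bound relative to the undisplaced system. One
configuration is retained per system. Interpolation paths hold every
atom except the hydrogen fixed and use 10 intermediates plus endpoints
(12 images); barriers are path maximum minus start/end, ties in the
maximum resolving to the lowest image index.

Parent→child trimming removes a terminal residue (plus its adjacent cap)
from a peptide system whose donor/acceptor/hydrogen motif lies elsewhere.
The residue's backbone unit adjacent to the cut — carbonyl C+O or amide
N+H, plus the alpha carbon — is retained and the alpha carbon's severed
substituents are replaced by hydrogens at 1.09 Å along the old bond
directions, yielding a genuine acetyl / NH–CH3 cap with every retained
atom, including the motif, at its original coordinates.

## Datasets and splits

Records persist as extended XYZ: a `Properties=` descriptor, frame keys
(energy, system id, stratification label, image index, split), and an
optional per-atom forces block. Formatting keeps round trips lossless to
10⁻¹⁰ Å and relative 10⁻¹² in energy; parse failures report the line.
The split unit is the radical system — all 12 images of a path inherit
their system's split, so barrier evaluation can never leak images across
subsets. Per-stratum quotas use largest-remainder rounding; systems are
keyed and sorted by id before a seeded shuffle, making the assignment
independent of record order. Strata smaller than the number of active
splits go to train with a warning.

## Dynamics

The integrator is BAOAB Langevin velocity-Verlet; defaults are a 0.5 fs
timestep, friction 0.01 fs⁻¹ and a 300 K setpoint, with Maxwell–Boltzmann
initial velocities (COM drift removed). The steering bias is
½k(q − q₀(t))² on q = d(H, donor) − d(H, acceptor) — a standard
sign-symmetric 1-D HAT coordinate, isolated behind `transfer_coordinate`
so alternatives are drop-in — with q₀ shifted linearly over `shift_steps`
then held. Preset spring constants are 1.0 ("medium") and 5.0 ("strong")
eV/Å². A transfer succeeds only if the hydrogen's nearest heavy-atom
neighbor (hydrogens never count) starts at the donor, switches to the
acceptor, and remains the acceptor through the final frame; `p_end` pools
replica verdicts, so with one system it is the per-replica success
fraction and across systems the pooled fraction.

## Evaluation metrics

Energy MAE is the mean absolute total-energy error in meV (per-atom
variant divides by atom count first). Force MAE pools all 3N Cartesian
components (a vector-norm variant is switchable) in meV/Å. Barrier MAE
recomputes ΔE_left/ΔE_right from predicted and reference profiles per
path and pools both sides equally; any constant per-path offset cancels
exactly, which is why indirect barrier predictions beat raw energies —
the offset-outlier flagger makes the converse visible by marking paths
whose error standard deviation is below 20% of a mean absolute offset
exceeding 0.1 eV. Transferability reports split at ≤50 vs >50 atoms
(50 counts as small) plus half-open atom-count bins. Learning curves are
fit as log MAE = log a − b log N by least squares, requiring ≥3 positive
points. Parent/child reports give per-side child−parent deviations, their
median and mean absolute value.

## Fixtures, and what passing tests show

The two-well fixture is a collinear C–H···C triatomic: two Morse wells
plus a stiff donor–acceptor tether. At the default 3.5 Å separation the
dense-scan barrier is ≈ 0.85 eV; below ≈ 3.2 Å the wells merge and no
barrier exists, so the fixture enforces its [2, 4] Å window. Its
1001-point dense scan is the ground truth for all interpolation tests.
Scripted trajectories realize an exact nearest-neighbor sequence for the
detection logic; synthetic prediction sets add Gaussian noise and
per-path offsets with closed-form expected MAEs (half-normal mean
σ√(2/π) for pure noise).

Passing on these fixtures demonstrates that the machinery — sampling
formulas, acceptance filters, geometry bookkeeping, event detection,
metric algebra — is correct and reproducible. It says nothing about real
peptide energetics: toy barriers, acceptance rates and transfer
probabilities have no chemical meaning, and results on real systems
depend entirely on the external engine that labels them.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen to exercise
every code path with comfortable statistics: 10⁴ distance draws, 10³
accepted normal-mode samples, 2 × 10³ posed systems for distribution
checks, 20 MD replicas of 2 × 10³ steps. All are parameters, and scale up
unchanged.

## Known limitations

* The toy potential omits dihedrals, electrostatics and solvent; the
  dielectric setting is plumbing for adapters.
* Uncapped termini are modeled neutral; charged variants and side-chain
  protonation states are not enumerated.
* Conformer ensembles come from distance-geometry embedding, not a
  systematic rotamer search; energy ordering is MMFF.
* Transition states are estimated by linear interpolation only — no
  optimization, NEB or saddle search.
* Parent→child trimming handles terminal residues of annotated linear
  peptides; proline's ring nitrogen at a C-terminal cut is not special-
  cased.
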