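"""Conformer selection and normal-mode sampling of non-equilibrium geometries.

The sampling stage turns each minimum-energy conformer into a pool of
thermally plausible distorted structures: the Hessian at the minimum is
mass-weighted and diagonalized, rigid translations/rotations are projected
out, and the molecule is displaced along a random superposition of its
vibrational modes.  Per mode ``m`` the mass-weighted displacement is

    d_m = s_m * sqrt(3 * c_m * kB * T / k_m)

with random sign ``s_m``, force constant ``k_m`` and random fractions
``c_m >= 0`` normalized to sum to one per sample (so the harmonic energy
of each draw is 3/2 kB T in total).  Candidates are kept only when no bond
stretches beyond a relative tolerance and the energy stays within
``max_rel_energy`` (default 5.0 eV) of the equilibrium structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry, KB_EV
from .calculators import Calculator, CalculatorError, bond_length_check


@dataclass
class Conformer:
    """A conformer geometry with its energy relative to the set minimum."""

    geometry: Geometry
    energy: float
    source_name: str = ""


@dataclass
class NormalModeSet:
    """Mass-weighted vibrational modes of a minimum.

    ``mode_vectors`` has shape (n_modes, 3N) with orthonormal rows in
    mass-weighted coordinates; ``force_constants`` are the corresponding
    eigenvalues in eV/(Å²·amu), sorted ascending.
    """

    mode_vectors: np.ndarray
    force_constants: np.ndarray
    n_modes: int
    is_minimum: bool = True


@dataclass
class NMSParams:
    """Normal-mode sampling controls.

    temperature
        Sampling temperature in K.  Default 500 K: hot enough to populate
        a broad energy band while the 5.0 eV cap does the final gating.
    max_rel_energy
        Retention bound in eV relative to the equilibrium conformer.
    max_rel_dev
        Relative bond-stretch tolerance of the geometric check.
    samples_per_conformer
        J, the number of accepted samples requested per conformer.
    fraction_mode
        "per_sample" normalizes the random fractions c_m to sum to 1 for
        each draw; "independent" leaves them as i.i.d. uniforms.
    min_force_constant
        Floor (eV/Å²·amu) applied to k_m in the displacement formula.
        Nearly-free modes (soft torsions) otherwise get huge linearized
        displacements that tear bonds apart long before the energy filter
        sees them; the floor caps their amplitude while leaving genuine
        vibrations untouched.
    """

    temperature: float = 500.0
    max_rel_energy: float = 5.0
    max_rel_dev: float = 0.2
    samples_per_conformer: int = 10
    seed: int = 0
    fraction_mode: str = "per_sample"
    min_force_constant: float = 0.1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_rel_energy <= 0:
            raise ValueError("max_rel_energy must be positive")
        if self.fraction_mode not in ("per_sample", "independent"):
            raise ValueError("fraction_mode must be 'per_sample' or 'independent'")


# ---------------------------------------------------------------------------
# Conformer generation / selection
# ---------------------------------------------------------------------------

def generate_conformers(smiles: str, n_conformers: int, seed: int = 0) -> list[Conformer]:
    """Generate an RDKit ETKDG conformer ensemble with MMFF energies.

    Energies are referenced to the lowest conformer.  This is the built-in
    conformer source; an external ensemble generator can be substituted by
    constructing :class:`Conformer` objects directly.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
    AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    props = AllChem.MMFFGetMoleculeProperties(mol)
    out = []
    for cid in ids:
        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
        e_ev = ff.CalcEnergy() * 0.04336  # kcal/mol -> eV
        conf = mol.GetConformer(cid)
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
              conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
        )
        geom = Geometry([a.GetSymbol() for a in mol.GetAtoms()], coords)
        out.append(Conformer(geom, e_ev, smiles))
    if not out:
        raise RuntimeError(f"conformer generation produced nothing for {smiles!r}")
    e_min = min(c.energy for c in out)
    for c in out:
        c.energy -= e_min
    return out


def select_conformers(
    conformers: list[Conformer],
    n_low: int = 5,
    n_random: int = 5,
    seed: int = 0,
) -> list[Conformer]:
    """Pick the ``n_low`` lowest-energy conformers plus ``n_random`` drawn
    uniformly without replacement from the remainder (C = 10 by default).

    Undersized ensembles are returned whole with a warning.
    """
    if not conformers:
        raise ValueError("empty conformer list")
    if n_low < 0 or n_random < 0:
        raise ValueError("n_low and n_random must be non-negative")
    if len(conformers) <= n_low + n_random:
        if len(conformers) < n_low + n_random:
            warnings.warn(
                f"only {len(conformers)} conformers available, "
                f"requested {n_low + n_random}"
            )
        return sorted(conformers, key=lambda c: c.energy)
    ranked = sorted(range(len(conformers)), key=lambda i: conformers[i].energy)
    low = ranked[:n_low]
    rest = ranked[n_low:]
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(rest), size=n_random, replace=False)
    return [conformers[i] for i in low] + [conformers[rest[i]] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------

def _rigid_body_basis(geometry: Geometry) -> np.ndarray:
    """Orthonormal mass-weighted basis of rigid translations and rotations."""
    n = geometry.n_atoms
    sqrt_m = np.sqrt(geometry.masses)
    rel = geometry.coordinates - geometry.center_of_mass()
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sqrt_m
        vecs.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = (sqrt_m[:, None] * np.cross(e, rel)).ravel()
        vecs.append(v)
    # Gram-Schmidt; linear molecules lose one rotation.
    basis = []
    for v in vecs:
        for b in basis:
            v = v - (b @ v) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.array(basis)


def is_linear(geometry: Geometry, moment_tol: float = 1e-3) -> bool:
    """Linearity via the smallest principal moment of inertia (amu·Å²)."""
    if geometry.n_atoms < 3:
        return True
    rel = geometry.coordinates - geometry.center_of_mass()
    m = geometry.masses
    inertia = np.einsum("a,ai,aj->ij", m, rel, rel)
    inertia = np.trace(inertia) * np.eye(3) - inertia
    return bool(np.linalg.eigvalsh(inertia)[0] < moment_tol)


def normal_modes(
    hessian: np.ndarray,
    masses: np.ndarray,
    geometry: Geometry,
    negative_tol: float = -1e-4,
) -> NormalModeSet:
    """Vibrational modes from a Cartesian Hessian.

    Mass-weights the Hessian, projects out the rigid-body subspace and
    keeps the 3N−6 (nonlinear) or 3N−5 (linear) vibrational eigenpairs,
    sorted ascending by force constant.  A retained eigenvalue below
    ``negative_tol`` triggers a not-a-minimum warning; numerically zero
    eigenvalues (|k| < 1e-8) are dropped, so a zero Hessian yields zero
    retained modes.
    """
    masses = np.asarray(masses, dtype=float)
    n3 = 3 * len(masses)
    hessian = np.asarray(hessian, dtype=float)
    if hessian.shape != (n3, n3):
        raise ValueError(f"hessian shape {hessian.shape} does not match 3N={n3}")
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    h_mw = hessian * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    basis = _rigid_body_basis(geometry)
    proj = np.eye(n3) - basis.T @ basis
    h_proj = proj @ h_mw @ proj
    h_proj = 0.5 * (h_proj + h_proj.T)
    evals, evecs = np.linalg.eigh(h_proj)
    n_rigid = basis.shape[0]
    order = np.argsort(np.abs(evals))
    keep = np.sort(order[n_rigid:])
    keep = [i for i in keep if abs(evals[i]) > 1e-8]
    k = evals[keep]
    v = evecs[:, keep].T
    asc = np.argsort(k)
    k, v = k[asc], v[asc]
    is_min = True
    expected = n3 - (5 if is_linear(geometry) else 6)
    if len(k) < max(expected, 0) or (len(k) and k[0] < negative_tol):
        warnings.warn(
            "Hessian does not look like a non-degenerate minimum "
            f"({len(k)} retained modes, lowest k = {k[0] if len(k) else 0:.3e})"
        )
        is_min = False
    return NormalModeSet(v, k, len(k), is_min)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def nms_sample(
    conformer: Conformer,
    modes: NormalModeSet,
    params: NMSParams,
    rng: np.random.Generator | None = None,
) -> Geometry:
    """Draw one normal-mode-displaced geometry (unfiltered)."""
    if modes.n_modes == 0:
        raise ValueError("empty mode set")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    c = rng.uniform(size=modes.n_modes)
    if params.fraction_mode == "per_sample":
        c = c / c.sum()
    signs = rng.choice([-1.0, 1.0], size=modes.n_modes)
    k_eff = np.maximum(modes.force_constants, params.min_force_constant)
    d = signs * np.sqrt(3.0 * c * KB_EV * params.temperature / k_eff)
    geom = conformer.geometry
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(geom.masses, 3))
    disp_mw = d @ modes.mode_vectors          # mass-weighted, 3N
    disp = (disp_mw * inv_sqrt_m).reshape(-1, 3)
    return geom.with_coordinates(geom.coordinates + disp)


def nms_accept(
    candidate: Geometry,
    conformer: Conformer,
    calculator: Calculator,
    params: NMSParams,
    bonded_pairs: list,
) -> tuple[bool, str]:
    """Acceptance filter: bonds intact and relative energy within bound.

    Returns (passed, reason) with reason in {"ok", "bond", "energy",
    "label-error"}.
    """
    if not bond_length_check(
        candidate, conformer.geometry, bonded_pairs, params.max_rel_dev
    ):
        return False, "bond"
    try:
        e_cand, _ = calculator.energy_forces(candidate)
        e_ref, _ = calculator.energy_forces(conformer.geometry)
    except CalculatorError:
        return False, "label-error"
    if e_cand - e_ref > params.max_rel_energy:
        return False, "energy"
    return True, "ok"


@dataclass
class NMSResult:
    geometries: list
    relative_energies: list
    n_attempts: int
    rejections: dict = field(default_factory=dict)

    @property
    def acceptance_rate(self) -> float:
        return len(self.geometries) / self.n_attempts if self.n_attempts else 0.0


def generate_nms_set(
    conformer: Conformer,
    modes: NormalModeSet,
    calculator: Calculator,
    params: NMSParams,
    bonded_pairs: list,
    retry_factor: int = 20,
) -> NMSResult:
    """Draw candidates until J are accepted or the retry budget runs out.

    The budget is ``retry_factor * J`` attempts; zero acceptances within
    the budget raise with the rejection-reason tally as diagnostics.
    """
    j = params.samples_per_conformer
    if j == 0:
        return NMSResult([], [], 0)
    budget = retry_factor * j
    if budget <= 0:
        raise ValueError("retry budget is zero but samples were requested")
    rng = np.random.default_rng(params.seed)
    e_ref, _ = calculator.energy_forces(conformer.geometry)
    accepted, energies = [], []
    rejections: dict = {}
    attempts = 0
    while len(accepted) < j and attempts < budget:
        attempts += 1
        candidate = nms_sample(conformer, modes, params, rng)
        ok, reason = nms_accept(candidate, conformer, calculator, params, bonded_pairs)
        if ok:
            accepted.append(candidate)
            e, _ = calculator.energy_forces(candidate)
            energies.append(e - e_ref)
        else:
            rejections[reason] = rejections.get(reason, 0) + 1
    if not accepted:
        raise RuntimeError(
            f"no samples accepted within {budget} attempts; rejections: {rejections}"
        )
    return NMSResult(accepted, energies, attempts, rejections)
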