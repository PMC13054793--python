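"""Peptide molecule catalog: SMILES construction, 3D embedding, optimization.

Covers the 20 standard amino acids and all 400 ordered dipeptides, each in
an uncapped form (free NH2 / COOH termini, neutral) and a capped form with
an acetyl group on the N-terminus and an N-methylamide (NH–CH3) on the
C-terminus, mimicking a protein-backbone context.  Ionizable side chains
(Arg, Lys, Asp, Glu, His) are built in their neutral forms and flagged.

3D coordinates come from RDKit's ETKDG embedding followed by an MMFF94
clean-up; both are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .geometry import Geometry
from .calculators import Calculator

RDLogger.DisableLog("rdApp.*")

#: Neutral side-chain fragments attached to the alpha carbon.
SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "G": None,
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "P": None,  # handled as a ring residue
    "S": "CO",
    "T": "C(C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "V": "C(C)C",
    "Y": "Cc1ccc(O)cc1",
}

AMINO_ACIDS = tuple(sorted(SIDE_CHAINS))

#: Side chains built here in neutral protonation; flagged on the spec.
IONIZABLE = frozenset("RKDEH")

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


class UnknownResidueError(ValueError):
    pass


class EmbeddingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MoleculeSpec:
    """Identity of a catalog molecule: sequence, capping state, SMILES."""

    residue_sequence: str
    capped: bool
    smiles: str
    name: str
    ionizable: bool = False


def _check_residue(code: str) -> None:
    if code not in SIDE_CHAINS:
        raise UnknownResidueError(
            f"unknown residue code {code!r}; expected one of {''.join(AMINO_ACIDS)}"
        )


def _residue_fragment(code: str, position: int) -> str:
    """SMILES fragment ``N...C(=O)`` for one residue in a chain.

    ``position`` (1-based) picks the ring-bond digit for proline, keeping
    ring closures unique along the chain.  Side-chain ring digits (1, 2)
    open and close inside their branch, so reuse across residues is legal
    SMILES.
    """
    if code == "P":
        digit = 8 if position % 2 else 9
        return f"N{digit}CCC[C@H]{digit}C(=O)"
    if code == "G":
        return "NCC(=O)"
    return f"N[C@@H]({SIDE_CHAINS[code]})C(=O)"


def _residue_heavy_count(code: str) -> int:
    """Heavy atoms contributed by one in-chain residue fragment."""
    if code == "P":
        return 7
    if code == "G":
        return 4
    return 4 + Chem.MolFromSmiles(SIDE_CHAINS[code]).GetNumAtoms()


def build_peptide_smiles(sequence: str, capped: bool) -> str:
    """SMILES for a linear peptide of standard residues."""
    for code in sequence:
        _check_residue(code)
    body = "".join(
        _residue_fragment(code, i + 1) for i, code in enumerate(sequence)
    )
    smiles = "CC(=O)" + body + "NC" if capped else body + "O"
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - guard
        raise ValueError(f"internal error: generated invalid SMILES {smiles!r}")
    return smiles


def peptide_residue_ids(sequence: str, capped: bool) -> np.ndarray:
    """Per-heavy-atom residue ids in SMILES atom order.

    Residues are numbered 1..L; the acetyl cap is 0 and the C-terminal
    N-methylamide cap is L+1.  RDKit preserves SMILES atom order, so ids
    follow directly from per-fragment atom counts.  The terminal hydroxyl
    oxygen of an uncapped peptide belongs to the last residue.
    """
    ids: list[int] = []
    if capped:
        ids += [0] * 3  # CH3, C, O of the acetyl group
    for i, code in enumerate(sequence):
        ids += [i + 1] * _residue_heavy_count(code)
    ids += [len(sequence) + 1] * 2 if capped else [len(sequence)]
    return np.array(ids, dtype=int)


def build_amino_acid_smiles(residue: str, capped: bool) -> str:
    """SMILES of a single amino acid, optionally acetyl/N-methylamide capped."""
    _check_residue(residue)
    return build_peptide_smiles(residue, capped)


def spec_for(sequence: str, capped: bool) -> MoleculeSpec:
    name = "-".join(THREE_LETTER[c] for c in sequence) + (
        "-capped" if capped else ""
    )
    return MoleculeSpec(
        residue_sequence=sequence,
        capped=capped,
        smiles=build_peptide_smiles(sequence, capped),
        name=name,
        ionizable=any(c in IONIZABLE for c in sequence),
    )


def enumerate_catalog(
    include_amino_acids: bool = True,
    include_dipeptides: bool = True,
    cap_modes: tuple = (False, True),
) -> list[MoleculeSpec]:
    """Enumerate the molecule catalog.

    Dipeptides are all ordered pairs of the 20 standard residues (20 × 20
    = 400, including homo-pairs).  Entries are unique by (sequence,
    capped).
    """
    cap_modes = tuple(dict.fromkeys(cap_modes))
    if not cap_modes or not (include_amino_acids or include_dipeptides):
        raise ValueError("select at least one molecule category and one cap mode")
    specs = []
    for capped in cap_modes:
        if include_amino_acids:
            for aa in AMINO_ACIDS:
                specs.append(spec_for(aa, capped))
        if include_dipeptides:
            for a in AMINO_ACIDS:
                for b in AMINO_ACIDS:
                    specs.append(spec_for(a + b, capped))
    return specs


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def _embed_mol(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EmbeddingError(f"SMILES does not parse: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"3D embedding failed for {smiles!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        pass  # keep the raw ETKDG geometry if MMFF has no parameters
    return mol


def _mol_to_geometry(mol: Chem.Mol) -> Geometry:
    conf = mol.GetConformer()
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
          conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())]
    )
    n_radical = sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms())
    return Geometry(
        elements,
        coords,
        charge=Chem.GetFormalCharge(mol),
        multiplicity=1 + n_radical,
    )


def embed_3d(spec: MoleculeSpec, seed: int = 0) -> Geometry:
    """Deterministically embed a catalog molecule in 3D."""
    return _mol_to_geometry(_embed_mol(spec.smiles, seed))


def embed_with_topology(
    spec_or_smiles, seed: int = 0, heavy_residue_ids: np.ndarray | None = None
) -> tuple[Geometry, list, np.ndarray | None]:
    """Embed and also return the bond list and per-atom residue ids.

    ``heavy_residue_ids`` annotates the heavy atoms in SMILES order (see
    :func:`peptide_residue_ids`); hydrogens inherit the id of their heavy
    neighbor.  Without annotations the third return value is None.
    """
    smiles = (
        spec_or_smiles.smiles
        if isinstance(spec_or_smiles, MoleculeSpec)
        else spec_or_smiles
    )
    mol = _embed_mol(smiles, seed)
    geom = _mol_to_geometry(mol)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    residue_ids = None
    if heavy_residue_ids is not None:
        n_heavy = len(heavy_residue_ids)
        residue_ids = np.empty(mol.GetNumAtoms(), dtype=int)
        residue_ids[:n_heavy] = heavy_residue_ids
        for atom in mol.GetAtoms():
            if atom.GetSymbol() == "H":
                heavy = atom.GetNeighbors()[0].GetIdx()
                residue_ids[atom.GetIdx()] = residue_ids[heavy]
    return geom, bonds, residue_ids


def embed_peptide(
    sequence: str, capped: bool, seed: int = 0
) -> tuple[Geometry, list, np.ndarray]:
    """Embed a peptide and return (geometry, bonds, per-atom residue ids)."""
    smiles = build_peptide_smiles(sequence, capped)
    return embed_with_topology(
        smiles, seed, peptide_residue_ids(sequence, capped)
    )


# ---------------------------------------------------------------------------
# Geometry optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizationResult:
    geometry: Geometry
    converged: bool
    n_steps: int
    energy: float
    max_force: float
    energy_history: list = field(default_factory=list)


def optimize_geometry(
    geom: Geometry,
    calculator: Calculator,
    gradient_tolerance: float = 1e-3,
    max_steps: int = 500,
) -> OptimizationResult:
    """Quasi-Newton (L-BFGS) minimization on the calculator's surface.

    Converged means the largest force component is at or below
    ``gradient_tolerance`` (eV/Å).  When ``max_steps`` is exhausted first,
    the best geometry so far is returned with ``converged=False`` and a
    warning.  Accepted line-search steps never increase the energy.
    """
    from scipy.optimize import minimize

    e0, f0 = calculator.energy_forces(geom)
    history = [e0]
    if max_steps == 0:
        return OptimizationResult(
            geom, False, 0, e0, float(np.abs(f0).max()), history
        )

    def fun(x):
        e, f = calculator.energy_forces(geom.with_coordinates(x.reshape(-1, 3)))
        return e, -f.ravel()

    res = minimize(
        fun,
        geom.coordinates.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=lambda xk: history.append(fun(xk)[0]),
        options={"maxiter": max_steps, "gtol": gradient_tolerance * 1e-2,
                 "ftol": 1e-14},
    )
    out = geom.with_coordinates(res.x.reshape(-1, 3))
    e, f = calculator.energy_forces(out)
    max_force = float(np.abs(f).max())
    converged = max_force <= gradient_tolerance
    if not converged:
        warnings.warn(
            f"optimization not converged: max |F| = {max_force:.2e} eV/Å "
            f"after {res.nit} steps"
        )
    return OptimizationResult(out, converged, int(res.nit), float(e), max_force, history)
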