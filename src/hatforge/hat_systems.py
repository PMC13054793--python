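"""Construction of HAT radical systems, reaction configurations and paths.

A radical system is one molecule (intra-HAT) or two molecules (inter-HAT)
together with the designated transferring hydrogen at position r_H, its
donor heavy atom, and the radical acceptor site r_0 created by removing a
hydrogen.  Reaction configurations displace the transferring hydrogen to
a random point between donor and acceptor; evaluation paths move it on a
straight, evenly spaced 12-image line from its start position to the
bonded end position r_1 next to the acceptor.  Barriers are read off a
path as the maximum energy relative to either end.

Atom indexing is 0-based everywhere, including serialized metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .geometry import (
    Geometry,
    GeometryError,
    HX_BOND_LENGTHS,
    infer_bonds,
    neighbor_map,
)
from .calculators import Calculator, CalculatorError, clash_check
from . import io as hio


class SystemConstructionError(RuntimeError):
    """A radical system or configuration could not be built."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class RadicalSystem:
    """A donor–H–acceptor motif embedded in one or two molecules."""

    geometry: Geometry
    molecule_boundaries: list          # [(start, stop), ...] half-open ranges
    h_index: int
    donor_index: int
    acceptor_index: int
    transfer_type: str                 # "intra" | "inter"
    system_label: str = ""
    bonded_pairs: list = field(default_factory=list)

    def validate(self) -> None:
        g = self.geometry
        if g.elements[self.h_index] != "H":
            raise GeometryError("h_index does not point at a hydrogen")
        for idx in (self.donor_index, self.acceptor_index):
            if g.elements[idx] == "H":
                raise GeometryError("donor/acceptor must be heavy atoms")
        if self.transfer_type not in ("intra", "inter"):
            raise GeometryError(f"bad transfer_type {self.transfer_type!r}")
        if self.transfer_type == "inter":
            if self._molecule_of(self.donor_index) == self._molecule_of(
                self.acceptor_index
            ):
                raise GeometryError(
                    "inter-HAT requires donor and acceptor in different molecules"
                )
        if not _nearest_h_ok(
            g, self.h_index, self.acceptor_index, self.bonded_pairs, tol=1e-9
        ):
            raise GeometryError(
                "another transferable hydrogen is closer to the acceptor "
                "than the transferring hydrogen"
            )

    def _molecule_of(self, atom: int) -> int:
        for m, (a, b) in enumerate(self.molecule_boundaries):
            if a <= atom < b:
                return m
        raise GeometryError(f"atom {atom} outside all molecule ranges")

    # -- serialization ------------------------------------------------

    def metadata(self) -> dict:
        return {
            "transfer_type": self.transfer_type,
            "system_label": self.system_label,
            "h_index": int(self.h_index),
            "donor_index": int(self.donor_index),
            "acceptor_index": int(self.acceptor_index),
            "molecule_boundaries": [list(map(int, b)) for b in self.molecule_boundaries],
            "bonded_pairs": [list(map(int, p)) for p in self.bonded_pairs],
            "index_base": 0,
        }

    def write(self, xyz_path, json_path) -> None:
        hio.write_extxyz(xyz_path, hio.Frame(self.geometry, {"kind": "radical_system"}))
        with open(json_path, "w") as fh:
            json.dump(self.metadata(), fh, indent=1)

    @classmethod
    def read(cls, xyz_path, json_path) -> "RadicalSystem":
        frame = hio.read_extxyz(xyz_path)[0]
        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(
            frame.geometry,
            [tuple(b) for b in meta["molecule_boundaries"]],
            meta["h_index"],
            meta["donor_index"],
            meta["acceptor_index"],
            meta["transfer_type"],
            meta.get("system_label", ""),
            [tuple(p) for p in meta.get("bonded_pairs", [])],
        )


@dataclass
class ReactionConfiguration:
    """A radical system with the hydrogen displaced to a sampled point."""

    system: RadicalSystem
    h_position: np.ndarray
    labels: object = None

    @property
    def geometry(self) -> Geometry:
        g = self.system.geometry.copy()
        g.coordinates[self.system.h_index] = self.h_position
        return g


@dataclass
class InterpolationPath:
    """Ordered images with only the transferring hydrogen moving."""

    system: RadicalSystem
    images: list
    energies: np.ndarray | None = None


@dataclass
class BarrierResult:
    """Forward/backward barrier estimates from a path's energy profile."""

    delta_e_left: float
    delta_e_right: float
    argmax_image: int


# ---------------------------------------------------------------------------
# Radical creation and donor selection
# ---------------------------------------------------------------------------

def make_radical(
    geom: Geometry, h_index: int, bonds: list | None = None
) -> tuple[Geometry, int, list]:
    """Delete a hydrogen, creating a doublet radical.

    Returns the trimmed geometry, the acceptor index (the deleted H's
    former heavy neighbor, remapped) and the remapped bond list.
    """
    if geom.elements[h_index] != "H":
        raise SystemConstructionError(f"atom {h_index} is not a hydrogen")
    bonds = infer_bonds(geom) if bonds is None else bonds
    heavies = [
        j
        for i, j in (p if p[0] == h_index else p[::-1] for p in bonds)
        if i == h_index and geom.elements[j] != "H"
    ]
    if len(heavies) != 1:
        raise SystemConstructionError(
            f"hydrogen {h_index} has {len(heavies)} heavy neighbors; need exactly 1"
        )
    acceptor = heavies[0]
    keep = [i for i in range(geom.n_atoms) if i != h_index]
    remap = {old: new for new, old in enumerate(keep)}
    new_geom = Geometry(
        [geom.elements[i] for i in keep],
        geom.coordinates[keep],
        geom.masses[keep],
        geom.charge,
        2,
    )
    new_bonds = [
        (remap[i], remap[j]) for i, j in bonds if h_index not in (i, j)
    ]
    return new_geom, remap[acceptor], new_bonds


def eligible_donors(
    geom: Geometry,
    bonds: list | None = None,
    allowed_heavy: frozenset = frozenset("CNOS"),
    exclude: set | None = None,
) -> list[int]:
    """Hydrogens bonded to an allowed heavy element (default C/N/O/S).

    The rule table is configuration: restrict ``allowed_heavy`` to model
    environment-dependent transfer conditions (e.g. drop "O" to exclude
    hydroxyl hydrogens).  ``exclude`` removes specific hydrogen indices,
    such as the acceptor's own former site.
    """
    bonds = infer_bonds(geom) if bonds is None else bonds
    nb = neighbor_map(geom.n_atoms, bonds)
    exclude = exclude or set()
    out = []
    for i, e in enumerate(geom.elements):
        if e != "H" or i in exclude:
            continue
        if any(geom.elements[j] in allowed_heavy for j in nb[i]):
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# Donor–acceptor distance sampling
# ---------------------------------------------------------------------------

#: χ² donor–acceptor distance law (all four numbers are configuration):
#: df=3 with scale 2.5 Å puts the pre-truncation mode at 2.5 Å; draws are
#: rejection-truncated to [CHI2_FLOOR, max_distance].
CHI2_DF = 3
CHI2_SCALE = 2.5
CHI2_FLOOR = 1.2


def sample_da_distance(
    rng_or_seed=0,
    max_distance: float = 4.0,
    min_distance: float = CHI2_FLOOR,
    df: int = CHI2_DF,
    scale: float = CHI2_SCALE,
    size: int | None = None,
):
    """Draw donor–acceptor distances from the truncated scaled-χ² law.

    Returns a scalar for ``size=None``, else an array of that length.
    """
    if max_distance <= min_distance:
        raise ValueError("max_distance must exceed the floor")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    n = 1 if size is None else size
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = stats.chi2.rvs(df, scale=scale, size=max(4 * (n - filled), 16),
                              random_state=rng)
        good = draw[(draw >= min_distance) & (draw <= max_distance)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return float(out[0]) if size is None else out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _nearest_h_ok(
    geom: Geometry,
    h_index: int,
    acceptor: int,
    bonds: list | None = None,
    tol: float = 0.0,
) -> bool:
    """True when no competing hydrogen is nearer the acceptor than the
    transferring one.

    Hydrogens covalently bonded to the acceptor itself are part of the
    radical site, not transfer competitors (a CH2• center keeps an H at
    bond distance), so they are exempt.
    """
    bonds = bonds if bonds is not None else infer_bonds(geom)
    acceptor_h = set()
    for i, j in bonds:
        if i == acceptor and geom.elements[j] == "H":
            acceptor_h.add(j)
        if j == acceptor and geom.elements[i] == "H":
            acceptor_h.add(i)
    r = geom.coordinates
    d_h = np.linalg.norm(r[h_index] - r[acceptor])
    for i, e in enumerate(geom.elements):
        if e == "H" and i != h_index and i not in acceptor_h:
            if np.linalg.norm(r[i] - r[acceptor]) < d_h - tol:
                return False
    return True


# ---------------------------------------------------------------------------
# System builders
# ---------------------------------------------------------------------------

def build_inter_system(
    radical_geom: Geometry,
    acceptor_index: int,
    donor_mol: Geometry,
    donor_h: int,
    seed: int = 0,
    radical_bonds: list | None = None,
    donor_bonds: list | None = None,
    max_distance: float = 4.0,
    budget: int = 200,
    system_label: str = "",
    clash_scale: float = 0.7,
) -> RadicalSystem:
    """Pose a donor molecule next to a radical to form an inter-HAT system.

    The donor molecule is rigidly rotated (uniform random orientation) and
    translated so its transferring hydrogen sits at a χ²-sampled distance
    (≤ ``max_distance``) from the radical site, in a uniformly random
    direction.  Poses are rejected until the merged system is clash-free
    and no other hydrogen is closer to the acceptor than the transferring
    one; the budget exhausting raises with diagnostics.
    """
    radical_bonds = infer_bonds(radical_geom) if radical_bonds is None else radical_bonds
    donor_bonds = infer_bonds(donor_mol) if donor_bonds is None else donor_bonds
    if donor_mol.elements[donor_h] != "H":
        raise SystemConstructionError("donor_h must be a hydrogen")
    nb = neighbor_map(donor_mol.n_atoms, donor_bonds)
    donor_heavies = [j for j in nb[donor_h] if donor_mol.elements[j] != "H"]
    if len(donor_heavies) != 1:
        raise SystemConstructionError("transferring H needs exactly one heavy neighbor")
    n1 = radical_geom.n_atoms
    merged_bonds = list(map(tuple, radical_bonds)) + [
        (i + n1, j + n1) for i, j in donor_bonds
    ]
    r0 = radical_geom.coordinates[acceptor_index]
    rng = np.random.default_rng(seed)
    failures = {"clash": 0, "nearest-h": 0}
    for _ in range(budget):
        d = sample_da_distance(rng, max_distance=max_distance)
        rot = _random_rotation(rng)
        centered = donor_mol.coordinates - donor_mol.coordinates[donor_h]
        posed = centered @ rot.T + r0 + d * _random_unit(rng)
        merged = Geometry(
            list(radical_geom.elements) + list(donor_mol.elements),
            np.vstack([radical_geom.coordinates, posed]),
            np.concatenate([radical_geom.masses, donor_mol.masses]),
            radical_geom.charge + donor_mol.charge,
            2,
        )
        ok, _pair = clash_check(merged, merged_bonds, scale=clash_scale)
        if not ok:
            failures["clash"] += 1
            continue
        if not _nearest_h_ok(merged, n1 + donor_h, acceptor_index, merged_bonds):
            failures["nearest-h"] += 1
            continue
        system = RadicalSystem(
            merged,
            [(0, n1), (n1, merged.n_atoms)],
            n1 + donor_h,
            n1 + donor_heavies[0],
            acceptor_index,
            "inter",
            system_label,
            merged_bonds,
        )
        system.validate()
        return system
    raise SystemConstructionError(
        f"no clash-free inter-HAT pose within {budget} attempts; {failures}"
    )


def build_intra_system(
    mol: Geometry,
    seed: int = 0,
    bonds: list | None = None,
    max_distance: float = 4.0,
    system_label: str = "",
    allowed_heavy: frozenset = frozenset("CNOS"),
) -> RadicalSystem:
    """Create an intra-HAT system inside one molecule.

    Enumerates (abstracted H, transferring H) pairs — the abstracted
    hydrogen's site becomes the acceptor radical — keeps those whose
    donor ≠ acceptor, whose H–acceptor distance is within ``max_distance``
    and where no other hydrogen is nearer the acceptor, then picks one
    uniformly at random.
    """
    bonds = infer_bonds(mol) if bonds is None else bonds
    hydrogens = eligible_donors(mol, bonds, allowed_heavy)
    nb = neighbor_map(mol.n_atoms, bonds)
    candidates = []
    for h_abs in hydrogens:
        trimmed, acceptor, new_bonds = make_radical(mol, h_abs, bonds)
        for h_tr in hydrogens:
            if h_tr == h_abs:
                continue
            h_new = h_tr - 1 if h_tr > h_abs else h_tr
            donor_heavies = [
                j for j in neighbor_map(trimmed.n_atoms, new_bonds)[h_new]
                if trimmed.elements[j] != "H"
            ]
            if len(donor_heavies) != 1 or donor_heavies[0] == acceptor:
                continue
            d = trimmed.distance(h_new, acceptor)
            if d > max_distance:
                continue
            if not _nearest_h_ok(trimmed, h_new, acceptor, new_bonds):
                continue
            candidates.append((h_abs, h_tr, trimmed, acceptor, h_new,
                               donor_heavies[0], new_bonds))
    if not candidates:
        raise SystemConstructionError(
            "no eligible intra-HAT donor/acceptor pair in this molecule"
        )
    rng = np.random.default_rng(seed)
    _, _, trimmed, acceptor, h_new, donor, new_bonds = candidates[
        rng.integers(len(candidates))
    ]
    system = RadicalSystem(
        trimmed,
        [(0, trimmed.n_atoms)],
        h_new,
        donor,
        acceptor,
        "intra",
        system_label,
        new_bonds,
    )
    system.validate()
    return system


# ---------------------------------------------------------------------------
# Reaction-configuration sampling and paths
# ---------------------------------------------------------------------------

def end_position(system: RadicalSystem) -> np.ndarray:
    """Bonded end point r_1: the reference X–H bond length from the
    acceptor along the acceptor→start-H direction."""
    g = system.geometry
    acc = g.coordinates[system.acceptor_index]
    direction = g.coordinates[system.h_index] - acc
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise GeometryError("transferring H coincides with the acceptor")
    length = HX_BOND_LENGTHS.get(g.elements[system.acceptor_index], 1.09)
    return acc + length * direction / norm


#: Extra sphere-radius margin (Å) beyond half the start–end span, so the
#: displacement function also reaches slightly off-path points.
SPHERE_MARGIN = 0.3


def displace_hydrogen(
    system: RadicalSystem,
    calculator: Calculator,
    max_rel_energy: float = 5.0,
    seed: int = 0,
    margin: float = SPHERE_MARGIN,
    budget: int = 200,
    radius: float | None = None,
    direction: np.ndarray | None = None,
) -> ReactionConfiguration:
    """Sample one reaction configuration (displacement function f).

    The hydrogen is moved to a point on a sphere centered at the midpoint
    of its start and end positions, with radius uniform on
    [0, span/2 + margin] and direction uniform on the sphere.  Candidates
    must pass the clash check and stay within ``max_rel_energy`` of the
    undisplaced system's energy.  ``radius``/``direction`` pin the draw
    (used by tests and by endpoint construction).
    """
    g = system.geometry
    start = g.coordinates[system.h_index]
    end = end_position(system)
    center = 0.5 * (start + end)
    half_span = 0.5 * np.linalg.norm(end - start)
    try:
        e_ref, _ = calculator.energy_forces(g)
    except CalculatorError as exc:
        raise SystemConstructionError(f"reference labeling failed: {exc}")
    rng = np.random.default_rng(seed)
    failures = {"clash": 0, "energy": 0}
    for _ in range(budget):
        r = rng.uniform(0.0, half_span + margin) if radius is None else radius
        u = _random_unit(rng) if direction is None else np.asarray(direction, float)
        pos = center + r * u
        candidate = g.copy()
        candidate.coordinates[system.h_index] = pos
        ok, _pair = clash_check(candidate, system.bonded_pairs)
        if not ok:
            failures["clash"] += 1
            continue
        e, _ = calculator.energy_forces(candidate)
        if e - e_ref > max_rel_energy:
            failures["energy"] += 1
            continue
        return ReactionConfiguration(system, pos)
    raise SystemConstructionError(
        f"no acceptable hydrogen placement within {budget} attempts; {failures}"
    )


def interpolate_path(
    system: RadicalSystem, n_intermediate: int = 10
) -> InterpolationPath:
    """Linear H-transfer path: start, ``n_intermediate`` evenly spaced
    intermediates, and the bonded end position (12 images by default)."""
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be non-negative")
    g = system.geometry
    start = g.coordinates[system.h_index].copy()
    end = end_position(system)
    n_img = n_intermediate + 2
    images = []
    for i in range(n_img):
        pos = start + (i / (n_img - 1)) * (end - start)
        img = g.copy()
        img.coordinates[system.h_index] = pos
        images.append(img)
    return InterpolationPath(system, images)


def path_energies(path: InterpolationPath, calculator: Calculator) -> np.ndarray:
    energies = np.array(
        [calculator.energy_forces(img)[0] for img in path.images]
    )
    path.energies = energies
    return energies


def compute_barriers(energies) -> BarrierResult:
    """ΔE_left = max(E) − E[0], ΔE_right = max(E) − E[-1].

    Ties in the maximum resolve to the lowest image index.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size < 2:
        raise ValueError("need at least two path energies")
    argmax = int(np.argmax(energies))
    e_max = energies[argmax]
    return BarrierResult(
        float(e_max - energies[0]), float(e_max - energies[-1]), argmax
    )


# ---------------------------------------------------------------------------
# Parent → child reduction
# ---------------------------------------------------------------------------

def reduce_to_child(
    parent: RadicalSystem,
    residue_ids: np.ndarray,
    remove_residue: int,
) -> tuple[RadicalSystem, np.ndarray]:
    """Trim a terminal residue off a parent peptide system, re-capping the
    cut with the backbone atoms it leaves behind.

    ``residue_ids`` annotates every atom of the parent geometry: 0 for the
    N-terminal acetyl cap, 1..L for residues, L+1 for the C-terminal
    N-methylamide cap (hydrogens carry their heavy neighbor's id).  The
    removed residue must be terminal and must not host the donor, acceptor
    or transferring hydrogen.

    Re-capping keeps the removed residue's backbone unit adjacent to the
    cut — carbonyl C+O (N-terminal removal) or amide N+H (C-terminal
    removal) — plus its alpha carbon, whose severed substituents are
    replaced by hydrogens at 1.09 Å along the old bond directions.  That
    converts the leftover backbone into a genuine acetyl / NH–CH3 cap
    while leaving every retained atom, including the D–H–A motif, at its
    original coordinates.

    Returns the child system and its per-atom residue ids (new cap atoms
    take the removed residue's id).
    """
    residue_ids = np.asarray(residue_ids, dtype=int)
    g = parent.geometry
    if residue_ids.shape[0] != g.n_atoms:
        raise ValueError("residue_ids length does not match atom count")
    n_res = int(residue_ids.max()) - 1  # ids 0..L+1
    if not (1 <= remove_residue <= n_res):
        raise ValueError(f"remove_residue must be in 1..{n_res}")
    if remove_residue not in (1, n_res):
        raise SystemConstructionError("only terminal residues can be removed")
    motif = {parent.h_index, parent.donor_index, parent.acceptor_index}
    cap_id = 0 if remove_residue == 1 else n_res + 1
    removal = set(np.where(
        (residue_ids == remove_residue) | (residue_ids == cap_id)
    )[0].tolist())
    if motif & removal:
        raise SystemConstructionError(
            "removable residue hosts donor/acceptor/transferring-H atoms; "
            "the D–H–A identity would change"
        )

    nb = neighbor_map(g.n_atoms, parent.bonded_pairs)
    cut = [
        (a, b)
        for a, b in parent.bonded_pairs
        for a, b in [(a, b) if a in removal else (b, a)]
        if a in removal and b not in removal
    ]
    if len(cut) != 1:
        raise SystemConstructionError(
            f"expected exactly one cut bond, found {len(cut)}"
        )
    a_rm, _a_keep = cut[0]

    # Backbone cap unit retained from the removed residue.
    keep_rm = {a_rm}
    alpha = None
    for j in nb[a_rm]:
        if j not in removal:
            continue
        if g.elements[j] in ("O", "H"):
            keep_rm.add(j)
        elif g.elements[j] == "C" and alpha is None:
            alpha = j
    if alpha is None:
        raise SystemConstructionError("could not locate the cap alpha carbon")
    keep_rm.add(alpha)
    new_h_positions = []
    for j in nb[alpha]:
        if j == a_rm:
            continue
        if j in removal and g.elements[j] == "H":
            keep_rm.add(j)
        else:
            direction = g.coordinates[j] - g.coordinates[alpha]
            direction /= np.linalg.norm(direction)
            new_h_positions.append(g.coordinates[alpha] + 1.09 * direction)

    keep = [i for i in range(g.n_atoms) if i not in removal or i in keep_rm]
    remap = {old: new for new, old in enumerate(keep)}
    n_keep = len(keep)
    elements = [g.elements[i] for i in keep] + ["H"] * len(new_h_positions)
    coords = np.vstack([g.coordinates[keep]] + [np.array(new_h_positions)]) \
        if new_h_positions else g.coordinates[keep]
    child_geom = Geometry(elements, coords, charge=g.charge, multiplicity=2)
    child_bonds = [
        (remap[i], remap[j])
        for i, j in parent.bonded_pairs
        if i in remap and j in remap
    ]
    child_bonds += [(remap[alpha], n_keep + k) for k in range(len(new_h_positions))]
    child_ids = np.array(
        [residue_ids[i] for i in keep] + [remove_residue] * len(new_h_positions)
    )

    # Remap molecule boundaries: contiguous keep ranges per molecule.
    boundaries = []
    offset = 0
    for a, b in parent.molecule_boundaries:
        kept = sum(1 for i in keep if a <= i < b)
        extra = len(new_h_positions) if (a <= alpha < b) else 0
        boundaries.append((offset, offset + kept + extra))
        offset += kept + extra
    # New hydrogens are appended at the end; only valid if the trimmed
    # molecule is the last one, which holds when removal targets the last
    # molecule or there is a single molecule.  Otherwise fall back to a
    # single range covering everything (the boundary is only used for the
    # inter/intra distinction, which trimming never changes).
    if len(parent.molecule_boundaries) > 1 and new_h_positions:
        mol_of_alpha = parent._molecule_of(alpha)
        if mol_of_alpha != len(parent.molecule_boundaries) - 1:
            boundaries = _boundaries_with_appended_h(
                parent, keep, remap, len(new_h_positions)
            )

    child = RadicalSystem(
        child_geom,
        boundaries,
        remap[parent.h_index],
        remap[parent.donor_index],
        remap[parent.acceptor_index],
        parent.transfer_type,
        parent.system_label + "|child",
        child_bonds,
    )
    if child_geom.n_atoms >= g.n_atoms:
        raise SystemConstructionError("child is not smaller than parent")
    child.validate()
    return child, child_ids


def _boundaries_with_appended_h(parent, keep, remap, n_new):
    """Boundary fallback when appended cap hydrogens break contiguity:
    treat each kept molecule range as-is and assign the appended atoms to
    the molecule of the cut."""
    boundaries = []
    offset = 0
    for a, b in parent.molecule_boundaries[:-1]:
        kept = sum(1 for i in keep if a <= i < b)
        boundaries.append((offset, offset + kept))
        offset += kept
    a, b = parent.molecule_boundaries[-1]
    kept = sum(1 for i in keep if a <= i < b)
    boundaries.append((offset, offset + kept + n_new))
    return boundaries
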