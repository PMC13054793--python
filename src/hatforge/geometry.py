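"""Cartesian molecular geometries and basic element data.

Internal unit conventions (used everywhere in the package):

* lengths in angstrom (Å)
* energies in electronvolt (eV)
* forces in eV/Å
* masses in unified atomic mass units (amu)
* time in femtoseconds (fs)

``KCAL_PER_MOL_EV`` is provided as a display conversion only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in eV/K.
KB_EV = 8.617333262e-5

#: 1 eV/Å of force acting on 1 amu, expressed as acceleration in Å/fs².
FORCE_TO_ACC = 9.648533212e-3

#: Display conversion: 1 kcal/mol in eV.
KCAL_PER_MOL_EV = 0.04336

#: Covalent radii in Å (Cordero et al. consensus values).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "F": 0.57, "Cl": 1.02, "P": 1.07,
}

#: Atomic masses in amu (IUPAC 2021 standard atomic weights).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "F": 18.998, "Cl": 35.45, "P": 30.974,
}

#: Reference X–H single-bond lengths in Å, used to place a transferred
#: hydrogen at its bonded end position next to the acceptor.
HX_BOND_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}


class GeometryError(ValueError):
    """Raised for malformed or physically invalid geometries."""


@dataclass
class Geometry:
    """Atomic elements plus Cartesian coordinates of one configuration.

    Parameters
    ----------
    elements
        Per-atom element symbols, length N.
    coordinates
        (N, 3) Cartesian positions in Å.
    masses
        Per-atom masses in amu; looked up from :data:`ATOMIC_MASSES`
        when omitted.
    charge
        Total integer charge.
    multiplicity
        Spin multiplicity (2S+1); radicals are doublets.
    """

    elements: list
    coordinates: np.ndarray
    masses: np.ndarray | None = None
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.elements = list(self.elements)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if n < 1:
            raise GeometryError("geometry must contain at least one atom")
        if self.coordinates.shape[0] != n:
            raise GeometryError(
                f"{n} elements but {self.coordinates.shape[0]} coordinate rows"
            )
        if self.masses is None:
            try:
                self.masses = np.array(
                    [ATOMIC_MASSES[e] for e in self.elements], dtype=float
                )
            except KeyError as exc:
                raise GeometryError(f"no mass tabulated for element {exc}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape[0] != n:
                raise GeometryError("masses length does not match element count")

    # -- convenience -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Geometry":
        return Geometry(
            list(self.elements),
            self.coordinates.copy(),
            self.masses.copy(),
            self.charge,
            self.multiplicity,
        )

    def with_coordinates(self, coordinates: np.ndarray) -> "Geometry":
        g = self.copy()
        g.coordinates = np.asarray(coordinates, dtype=float).reshape(-1, 3)
        if g.coordinates.shape[0] != g.n_atoms:
            raise GeometryError("coordinate shape mismatch")
        return g

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))

    def min_distance(self) -> float:
        """Smallest interatomic distance; inf for a single atom."""
        if self.n_atoms < 2:
            return float("inf")
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(self.n_atoms, k=1)
        return float(r[iu].min())

    def validate(self, min_dist: float = 0.5) -> None:
        """Assert the no-overlap invariant (atoms ≥ ``min_dist`` Å apart)."""
        m = self.min_distance()
        if m < min_dist:
            raise GeometryError(
                f"atoms closer than {min_dist} Å (minimum distance {m:.3f} Å)"
            )

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coordinates / self.masses.sum()


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError as exc:
        raise GeometryError(f"no covalent radius tabulated for {element}") from exc


def infer_bonds(geom: Geometry, scale: float = 1.25) -> list[tuple[int, int]]:
    """Infer a bond list from interatomic distances.

    Two atoms are bonded when their distance is below ``scale`` times the
    sum of their covalent radii — the usual distance criterion when no
    explicit topology is available.
    """
    bonds = []
    r = geom.coordinates
    radii = np.array([covalent_radius(e) for e in geom.elements])
    for i in range(geom.n_atoms):
        for j in range(i + 1, geom.n_atoms):
            if np.linalg.norm(r[i] - r[j]) <= scale * (radii[i] + radii[j]):
                bonds.append((i, j))
    return bonds


def neighbor_map(n_atoms: int, bonds) -> dict:
    nb = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        nb[i].add(j)
        nb[j].add(i)
    return nb
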