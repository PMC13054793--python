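"""Energy/force providers and the geometric acceptance checks.

The central contract is :class:`Calculator`: anything with an
``energy_forces(geometry) -> (energy, forces)`` method.  The package ships
:class:`ToyPotential`, an analytic reactive surrogate used for desk-scale
work in place of semi-empirical or DFT engines: harmonic bonds, harmonic
angles and Lennard-Jones nonbonded terms, with the donor–H and acceptor–H
interactions switched to dissociable Morse wells when a reactive triplet
is declared, so a hydrogen can actually transfer on the toy surface.

Toy energetics are NOT chemistry — they exist so every pipeline stage has
exact, reproducible labels.  Real labeling engines plug in through the
registry (:func:`register_calculator` / :func:`get_calculator`); the
"xtb" and "turbomole-bmk" names are declared as adapters that raise until
an adapter implementation is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .geometry import (
    Geometry,
    GeometryError,
    HX_BOND_LENGTHS,
    covalent_radius,
    neighbor_map,
)


@runtime_checkable
class Calculator(Protocol):
    """Energy/force provider contract."""

    def energy_forces(self, geom: Geometry) -> tuple[float, np.ndarray]:
        ...


@dataclass
class CalculatorSettings:
    """Engine-level options carried alongside labels.

    ``dielectric`` is the relative permittivity an implicit-solvent engine
    should use (default 10, approximating a protein-like environment).
    The toy potential has no solvent model and ignores it.
    """

    dielectric: float = 10.0
    engine: str = "toy"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")

    def provenance(self) -> str:
        items = ",".join(f"{k}={v}" for k, v in sorted(self.extra.items()))
        return f"{self.engine}[eps={self.dielectric:g};{items}]"


@dataclass
class LabeledConfiguration:
    """A geometry with its energy/force labels and their provenance."""

    geometry: Geometry
    energy: float
    forces: np.ndarray
    provenance: str = "toy"

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
        if self.forces.shape[0] != self.geometry.n_atoms:
            raise ValueError("forces length does not match atom count")


class CalculatorError(RuntimeError):
    """Engine failure while evaluating a configuration."""


class EngineNotInstalledError(CalculatorError):
    pass


# ---------------------------------------------------------------------------
# Toy reactive potential
# ---------------------------------------------------------------------------

#: Default toy force-field constants (config, not normative chemistry).
DEFAULT_BOND_K = 20.0     # eV/Å²
DEFAULT_ANGLE_K = 2.0     # eV/rad²
DEFAULT_LJ_EPS = 0.003    # eV
DEFAULT_MORSE_DE = 4.0    # eV   (chosen so toy HAT barriers land at 0.5–3 eV)
DEFAULT_MORSE_A = 2.0     # 1/Å


def _lj_sigma(e1: str, e2: str) -> float:
    return 1.8 * (covalent_radius(e1) + covalent_radius(e2))


class ToyPotential:
    """Analytic reactive test potential.

    Equilibrium bond lengths and angles are taken from a reference
    geometry at construction, so the reference is (close to) a minimum of
    its own toy surface.  With ``reactive_triplet=(donor, h, acceptor)``
    the H–donor and H–acceptor interactions become Morse potentials with
    a common well depth, producing a symmetric double well along the
    transfer coordinate when the geometry is symmetric.

    Parameters marked as module constants above are configuration knobs;
    none are fit to reproduce real energetics.
    """

    def __init__(
        self,
        reference: Geometry,
        bonded_pairs: list,
        reactive_triplet: tuple | None = None,
        bond_k: float = DEFAULT_BOND_K,
        angle_k: float = DEFAULT_ANGLE_K,
        lj_eps: float = DEFAULT_LJ_EPS,
        morse_de: float = DEFAULT_MORSE_DE,
        morse_a: float = DEFAULT_MORSE_A,
        extra_bonds: list | None = None,
    ):
        n = reference.n_atoms
        for i, j in bonded_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"bonded pair ({i},{j}) out of range for {n} atoms")
        self.n_atoms = n
        self.elements = list(reference.elements)
        self.reactive_triplet = reactive_triplet
        self.bond_k = bond_k
        self.angle_k = angle_k
        self.lj_eps = lj_eps
        self.morse_de = morse_de
        self.morse_a = morse_a
        self.settings = CalculatorSettings(engine="toy")

        reactive_pairs = set()
        self.morse_terms = []  # (i_heavy, h, r_e)
        if reactive_triplet is not None:
            donor, h, acceptor = reactive_triplet
            for idx in reactive_triplet:
                if not 0 <= idx < n:
                    raise IndexError("reactive triplet index out of range")
            for heavy in (donor, acceptor):
                r_e = HX_BOND_LENGTHS.get(self.elements[heavy], 1.09)
                self.morse_terms.append((heavy, h, r_e))
                reactive_pairs.add(frozenset((heavy, h)))

        # Harmonic bonds: reference distances, minus any pair promoted to Morse.
        self.bonds = []
        for i, j in sorted(set(tuple(sorted(p)) for p in bonded_pairs)):
            if frozenset((i, j)) in reactive_pairs:
                continue
            self.bonds.append((i, j, reference.distance(i, j)))
        for i, j, r0 in extra_bonds or []:
            self.bonds.append((i, j, r0))

        # Harmonic angles from bonded neighbor pairs; drop angles that
        # involve a reactive H (it moves far from the reference).
        nb = neighbor_map(n, [(i, j) for i, j, _ in self.bonds])
        h_reactive = reactive_triplet[1] if reactive_triplet else None
        self.angles = []
        for j in range(n):
            neigh = sorted(nb[j])
            for a in range(len(neigh)):
                for b in range(a + 1, len(neigh)):
                    i, k = neigh[a], neigh[b]
                    if h_reactive in (i, j, k):
                        continue
                    self.angles.append((i, j, k, _angle(reference.coordinates, i, j, k)))

        # LJ on everything not bonded, not 1-3, not reactive.
        excluded = set(frozenset((i, j)) for i, j, _ in self.bonds) | reactive_pairs
        for i, j, k, _ in self.angles:
            excluded.add(frozenset((i, k)))
        self.lj_pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) in excluded:
                    continue
                self.lj_pairs.append((i, j, _lj_sigma(self.elements[i], self.elements[j])))

    # -- evaluation --------------------------------------------------

    def energy_forces(self, geom: Geometry) -> tuple[float, np.ndarray]:
        if geom.n_atoms != self.n_atoms:
            raise CalculatorError(
                f"geometry has {geom.n_atoms} atoms, potential built for {self.n_atoms}"
            )
        r = geom.coordinates
        energy = 0.0
        forces = np.zeros_like(r)

        for i, j, r0 in self.bonds:
            d = r[i] - r[j]
            dist = np.linalg.norm(d)
            energy += 0.5 * self.bond_k * (dist - r0) ** 2
            g = self.bond_k * (dist - r0) * d / dist
            forces[i] -= g
            forces[j] += g

        for i, j, k, t0 in self.angles:
            e, gi, gj, gk = _angle_term(r, i, j, k, t0, self.angle_k)
            energy += e
            forces[i] -= gi
            forces[j] -= gj
            forces[k] -= gk

        for heavy, h, r_e in self.morse_terms:
            d = r[h] - r[heavy]
            dist = np.linalg.norm(d)
            ex = np.exp(-self.morse_a * (dist - r_e))
            energy += self.morse_de * (1.0 - ex) ** 2
            dV = 2.0 * self.morse_de * self.morse_a * (1.0 - ex) * ex
            g = dV * d / dist
            forces[h] -= g
            forces[heavy] += g

        for i, j, sigma in self.lj_pairs:
            d = r[i] - r[j]
            dist = np.linalg.norm(d)
            sr6 = (sigma / dist) ** 6
            energy += 4.0 * self.lj_eps * (sr6 * sr6 - sr6)
            dV = 4.0 * self.lj_eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / dist
            g = dV * d / dist
            forces[i] -= g
            forces[j] += g

        return float(energy), forces


def _angle(r, i, j, k) -> float:
    u = r[i] - r[j]
    v = r[k] - r[j]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _angle_term(r, i, j, k, t0, ka):
    """Harmonic angle energy and Cartesian gradients (not forces)."""
    u = r[i] - r[j]
    v = r[k] - r[j]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh = u / nu
    vh = v / nv
    c = np.clip(np.dot(uh, vh), -1.0, 1.0)
    s = np.sqrt(max(1.0 - c * c, 1e-12))
    theta = np.arccos(c)
    e = 0.5 * ka * (theta - t0) ** 2
    dE = ka * (theta - t0)
    dti = (c * uh - vh) / (nu * s)
    dtk = (c * vh - uh) / (nv * s)
    dtj = -dti - dtk
    return e, dE * dti, dE * dtj, dE * dtk


def toy_energy_forces(
    geom: Geometry,
    bonded_pairs: list,
    reactive_triplet: tuple | None = None,
    reference: Geometry | None = None,
    **kwargs,
) -> tuple[float, np.ndarray]:
    """One-shot toy evaluation; equilibrium values from ``reference``
    (default: ``geom`` itself)."""
    pot = ToyPotential(
        reference if reference is not None else geom,
        bonded_pairs,
        reactive_triplet,
        **kwargs,
    )
    return pot.energy_forces(geom)


# ---------------------------------------------------------------------------
# Hessian and geometric checks
# ---------------------------------------------------------------------------

def finite_difference_hessian(
    geom: Geometry, calculator: Calculator, step: float = 1e-3
) -> np.ndarray:
    """Central-difference Hessian in eV/Å², symmetrized as (H+Hᵀ)/2."""
    if step <= 0:
        raise ValueError("step must be positive")
    n3 = 3 * geom.n_atoms
    hess = np.empty((n3, n3))
    coords = geom.coordinates.copy()
    for idx in range(n3):
        a, x = divmod(idx, 3)
        for sign, store in ((+1, 0), (-1, 1)):
            c = coords.copy()
            c[a, x] += sign * step
            _, f = calculator.energy_forces(geom.with_coordinates(c))
            if store == 0:
                f_plus = f.ravel()
            else:
                f_minus = f.ravel()
        # H = d²E/dx² = -dF/dx
        hess[:, idx] = -(f_plus - f_minus) / (2.0 * step)
    return 0.5 * (hess + hess.T)


#: Floor (Å) applied to the clash threshold of any pair involving hydrogen;
#: 0.7 × the H covalent-radius sum would otherwise be far below contact.
CLASH_H_FLOOR = 0.9


def clash_check(
    geom: Geometry,
    bonded_pairs: list,
    scale: float = 0.7,
    h_floor: float = CLASH_H_FLOOR,
) -> tuple[bool, tuple | None]:
    """Steric-clash test on all non-bonded pairs.

    Fails when a non-bonded pair is closer than ``scale`` times the sum of
    the two covalent radii (with an ``h_floor`` Å floor for pairs involving
    H).  Returns ``(passed, offending_pair_or_None)``.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    bonded = set(frozenset(p) for p in bonded_pairs)
    r = geom.coordinates
    for i in range(geom.n_atoms):
        for j in range(i + 1, geom.n_atoms):
            if frozenset((i, j)) in bonded:
                continue
            thr = scale * (
                covalent_radius(geom.elements[i]) + covalent_radius(geom.elements[j])
            )
            if "H" in (geom.elements[i], geom.elements[j]):
                thr = max(thr, h_floor)
            if np.linalg.norm(r[i] - r[j]) < thr:
                return False, (i, j)
    return True, None


def bond_length_check(
    candidate: Geometry,
    reference: Geometry,
    bonded_pairs: list,
    max_rel_dev: float = 0.2,
) -> bool:
    """True unless any bonded distance deviates from its reference value
    by more than ``max_rel_dev`` (relative).  Forbids broken bonds while
    allowing thermal stretch."""
    if candidate.n_atoms != reference.n_atoms or list(candidate.elements) != list(
        reference.elements
    ):
        raise GeometryError("candidate and reference are not atom-aligned")
    for i, j in bonded_pairs:
        r_ref = reference.distance(i, j)
        if abs(candidate.distance(i, j) - r_ref) > max_rel_dev * r_ref:
            return False
    return True


# ---------------------------------------------------------------------------
# Engine registry
# ---------------------------------------------------------------------------

_REGISTRY: dict = {}


def register_calculator(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_calculator(name: str, **kwargs) -> Calculator:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise EngineNotInstalledError(
            f"no calculator registered under {name!r}; known: {sorted(_REGISTRY)}"
        )
    return factory(**kwargs)


def _missing_engine(name):
    def factory(**kwargs):
        raise EngineNotInstalledError(
            f"engine {name!r} is declared as an adapter interface but is not "
            "installed in this environment"
        )

    return factory


register_calculator("toy", lambda **kw: ToyPotential(**kw))
register_calculator("xtb", _missing_engine("xtb"))
register_calculator("turbomole-bmk", _missing_engine("turbomole-bmk"))
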