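"""Deterministic toy fixtures: reference systems with exactly known answers.

Everything here is SYNTHETIC.  The fixtures exercise the pipeline — toy
two-well HAT systems whose true barrier is available from a dense 1-D
scan, scripted trajectories realizing a prescribed nearest-neighbor
sequence, and prediction sets with closed-form expected errors — so that
every module can be tested without an external labeling engine.  Toy
labels are not chemistry and must never be mistaken for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, HX_BOND_LENGTHS
from .calculators import ToyPotential
from .hat_systems import RadicalSystem, compute_barriers, BarrierResult
from .dynamics import Trajectory
from .evaluation import PredictionSet


def make_two_well_hat_system(
    d_da: float = 3.5,
    well_depth: float = 4.0,
    morse_a: float = 2.0,
    tether: bool = True,
    seed: int = 0,
) -> tuple[RadicalSystem, ToyPotential]:
    """Collinear C–H···C donor/acceptor system on a double-well surface.

    The transferring hydrogen feels two Morse wells (depth ``well_depth``
    eV, width 1/``morse_a`` Å) centered on the donor and acceptor carbons
    ``d_da`` Å apart; for d_da ≳ 3.2 Å the two wells are separated by a
    barrier whose exact height is available from :func:`dense_scan_barrier`.
    ``tether=True`` adds a stiff harmonic donor–acceptor restraint at
    d_da so the wells stay put during dynamics.  d_da must lie in the
    sampler's [2, 4] Å window.
    """
    if not 2.0 <= d_da <= 4.0:
        raise ValueError("d_da must lie in [2, 4] Å")
    r_e = HX_BOND_LENGTHS["C"]
    geom = Geometry(
        ["C", "H", "C"],
        np.array([[0.0, 0.0, 0.0], [r_e, 0.0, 0.0], [d_da, 0.0, 0.0]]),
        charge=0,
        multiplicity=2,
    )
    pot = ToyPotential(
        geom,
        bonded_pairs=[(0, 1)],
        reactive_triplet=(0, 1, 2),
        morse_de=well_depth,
        morse_a=morse_a,
        extra_bonds=[(0, 2, d_da)] if tether else None,
    )
    system = RadicalSystem(
        geom,
        [(0, 2), (2, 3)],
        h_index=1,
        donor_index=0,
        acceptor_index=2,
        transfer_type="inter",
        system_label=f"two-well-d{d_da:g}",
        bonded_pairs=[(0, 1), (0, 2)] if tether else [(0, 1)],
    )
    system.validate()
    return system, pot


def dense_scan_barrier(
    system: RadicalSystem, calculator, n_points: int = 1001
) -> BarrierResult:
    """Ground-truth barrier by a dense scan of the H along the start→end
    line — the oracle the 12-image interpolation is compared against."""
    from .hat_systems import end_position

    g = system.geometry
    start = g.coordinates[system.h_index].copy()
    end = end_position(system)
    energies = []
    probe = g.copy()
    for t in np.linspace(0.0, 1.0, n_points):
        probe.coordinates[system.h_index] = start + t * (end - start)
        energies.append(calculator.energy_forces(probe)[0])
    return compute_barriers(energies)


def make_scripted_trajectory(
    events: list,
    n_frames: int | None = None,
    heavy_separation: float = 6.0,
) -> Trajectory:
    """A trajectory whose nearest-heavy-neighbor sequence is prescribed.

    ``events`` is a list of (frame, heavy_atom_index) with strictly
    increasing frames; from each event's frame onward the transferring
    hydrogen (atom 1) sits 1.0 Å from that heavy atom (donor=0 at the
    origin, acceptor=2 at ``heavy_separation`` Å).  Before the first
    event the hydrogen sits on the donor.
    """
    frames_idx = [f for f, _ in events]
    if any(b <= a for a, b in zip(frames_idx, frames_idx[1:])):
        raise ValueError("event frames must be strictly increasing")
    for f, who in events:
        if who not in (0, 2):
            raise ValueError("events must name the donor (0) or acceptor (2)")
    n_frames = (frames_idx[-1] + 10 if events else 10) if n_frames is None else n_frames
    if events and frames_idx[-1] >= n_frames:
        raise ValueError("event beyond trajectory length")
    positions = {0: np.array([1.0, 0.0, 0.0]),
                 2: np.array([heavy_separation - 1.0, 0.0, 0.0])}
    frames = []
    current = 0
    pending = list(events)
    for f in range(n_frames):
        while pending and pending[0][0] == f:
            current = pending.pop(0)[1]
        coords = np.array(
            [[0.0, 0.0, 0.0], positions[current], [heavy_separation, 0.0, 0.0]]
        )
        frames.append(Geometry(["C", "H", "C"], coords, multiplicity=2))
    zeros = np.zeros(n_frames)
    return Trajectory(frames, zeros, zeros, zeros, zeros, 1.0, 1, 0)


def make_synthetic_predictions(
    ref: PredictionSet,
    paths: dict | None = None,
    energy_noise: float = 0.0,
    force_noise: float = 0.0,
    per_path_offset: float = 0.0,
    seed: int = 0,
) -> PredictionSet:
    """Perturb reference labels into a synthetic "model" prediction set.

    Each configuration's energy gets i.i.d. Gaussian noise of width
    ``energy_noise`` eV plus a constant ±``per_path_offset`` eV shared by
    all members of its path (sign random per path); forces get i.i.d.
    Gaussian noise of width ``force_noise`` eV/Å.  With pure offsets the
    expected energy MAE is the offset and the expected barrier MAE is 0
    (offsets cancel within a path); with pure Gaussian noise the expected
    energy MAE is σ·√(2/π), the half-normal mean.
    """
    if energy_noise < 0 or force_noise < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    offset_of = {}
    if paths:
        grouped = set()
        for pid in sorted(paths):
            sign = rng.choice([-1.0, 1.0])
            for cid in paths[pid]:
                offset_of[cid] = sign * per_path_offset
                grouped.add(cid)
        for cid in sorted(set(ref.energies) - grouped):
            offset_of[cid] = rng.choice([-1.0, 1.0]) * per_path_offset
    else:
        for cid in sorted(ref.energies):
            offset_of[cid] = rng.choice([-1.0, 1.0]) * per_path_offset
    energies = {
        cid: ref.energies[cid] + offset_of[cid] + rng.normal(scale=energy_noise)
        if energy_noise > 0
        else ref.energies[cid] + offset_of[cid]
        for cid in sorted(ref.energies)
    }
    forces = {}
    for cid in sorted(ref.forces):
        f = np.asarray(ref.forces[cid], dtype=float)
        if force_noise > 0:
            f = f + rng.normal(scale=force_noise, size=f.shape)
        forces[cid] = f
    return PredictionSet(energies, forces, provenance="synthetic")
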