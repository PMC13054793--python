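"""NVT molecular dynamics with optional steered-HAT biasing.

The integrator is BAOAB Langevin velocity-Verlet (Leimkuhler–Matthews
splitting) over any calculator satisfying the energy/force contract.
Steering applies a one-dimensional harmonic bias along the donor–acceptor
transfer coordinate

    q = |r_H − r_donor| − |r_H − r_acceptor|

(negative while the hydrogen sits on the donor, positive once it has
transferred), whose reference value is shifted linearly from ``q_initial``
to ``q_target`` over ``shift_steps`` steps and then held.

A HAT event is scored from the trajectory alone: the transfer succeeds if
the hydrogen's nearest *heavy*-atom neighbor switches from the original
donor to the intended acceptor and remains the acceptor until the final
frame.  ``p_end`` pools such verdicts over replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry, KB_EV, FORCE_TO_ACC
from .calculators import Calculator
from .hat_systems import RadicalSystem

#: Preset spring constants (eV/Å²) for the steering modes.
STEERING_SPRING = {"medium": 1.0, "strong": 5.0}


@dataclass
class SteeringSchedule:
    """Harmonic bias with a linearly moving reference.

    ``mode`` is a convenience preset ("none" disables the bias, "medium"
    and "strong" pick the spring constants above); an explicit
    ``spring_constant`` overrides the preset.
    """

    spring_constant: float = 1.0
    q_initial: float = -1.0
    q_target: float = 1.0
    shift_steps: int = 1000
    mode: str = "custom"

    def __post_init__(self):
        if self.mode != "none" and self.shift_steps < 1:
            raise ValueError("shift_steps must be >= 1")

    @classmethod
    def none(cls) -> "SteeringSchedule":
        return cls(0.0, 0.0, 0.0, 1, "none")

    @classmethod
    def preset(cls, mode: str, q_initial: float, q_target: float,
               shift_steps: int) -> "SteeringSchedule":
        if mode == "none":
            return cls.none()
        return cls(STEERING_SPRING[mode], q_initial, q_target, shift_steps, mode)

    def reference(self, step: int) -> float:
        frac = min(step / self.shift_steps, 1.0)
        return self.q_initial + frac * (self.q_target - self.q_initial)


@dataclass
class Trajectory:
    frames: list
    potential_energies: np.ndarray
    kinetic_energies: np.ndarray
    bias_energies: np.ndarray
    temperature_series: np.ndarray
    timestep: float
    stride: int
    seed: int


@dataclass
class HATVerdict:
    success: bool
    switch_frame: int | None
    final_neighbor: int


class DynamicsInstability(RuntimeError):
    def __init__(self, frame: int):
        super().__init__(f"non-finite energy or force at frame {frame} (instability)")
        self.frame = frame


# ---------------------------------------------------------------------------
# Transfer coordinate and bias
# ---------------------------------------------------------------------------

def transfer_coordinate(
    geom: Geometry, donor: int, h: int, acceptor: int
) -> float:
    """Signed 1-D HAT coordinate q = d(H, donor) − d(H, acceptor)."""
    r = geom.coordinates
    d_d = np.linalg.norm(r[h] - r[donor])
    d_a = np.linalg.norm(r[h] - r[acceptor])
    if d_d < 1e-9 or d_a < 1e-9:
        raise ValueError("coincident atoms in transfer coordinate")
    return float(d_d - d_a)


def steering_bias(
    geom: Geometry,
    donor: int,
    h: int,
    acceptor: int,
    step: int,
    schedule: SteeringSchedule,
) -> tuple[float, np.ndarray]:
    """Bias energy ½k(q − q₀(step))² and its exact negative gradient."""
    if schedule.mode == "none" or schedule.spring_constant == 0.0:
        return 0.0, np.zeros_like(geom.coordinates)
    if step < 0:
        raise ValueError("step must be non-negative")
    r = geom.coordinates
    vd = r[h] - r[donor]
    va = r[h] - r[acceptor]
    dd = np.linalg.norm(vd)
    da = np.linalg.norm(va)
    q = dd - da
    q0 = schedule.reference(step)
    k = schedule.spring_constant
    energy = 0.5 * k * (q - q0) ** 2
    pref = k * (q - q0)
    forces = np.zeros_like(r)
    ud = vd / dd
    ua = va / da
    forces[h] -= pref * (ud - ua)
    forces[donor] -= pref * (-ud)
    forces[acceptor] -= pref * ua
    return float(energy), forces


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def run_nvt(
    system: RadicalSystem,
    calculator: Calculator,
    temperature: float = 300.0,
    timestep: float = 0.5,
    n_steps: int = 1000,
    seed: int = 0,
    schedule: SteeringSchedule | None = None,
    friction: float = 0.01,
    stride: int = 1,
) -> Trajectory:
    """Langevin (BAOAB) NVT dynamics, optionally steered.

    ``timestep`` in fs, ``friction`` in 1/fs.  Initial velocities are
    Maxwell–Boltzmann at the setpoint with the center-of-mass drift
    removed.  Frames are recorded every ``stride`` steps (n_steps/stride
    + 1 including the initial frame).  Non-finite energies or forces
    abort with the frame index.
    """
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    schedule = SteeringSchedule.none() if schedule is None else schedule
    rng = np.random.default_rng(seed)
    geom = system.geometry.copy()
    m = geom.masses[:, None]
    dof = 3 * geom.n_atoms

    sigma_v = np.sqrt(FORCE_TO_ACC * KB_EV * temperature / geom.masses)[:, None]
    vel = rng.normal(size=(geom.n_atoms, 3)) * sigma_v
    vel -= (geom.masses @ vel) / geom.masses.sum()

    c1 = np.exp(-friction * timestep)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))

    def eval_all(step):
        e_pot, f = calculator.energy_forces(geom)
        e_bias, f_bias = steering_bias(
            geom, system.donor_index, system.h_index, system.acceptor_index,
            step, schedule,
        )
        return e_pot, e_bias, f + f_bias

    def kinetic(v):
        return 0.5 * float((geom.masses * (v * v).sum(axis=1)).sum()) / FORCE_TO_ACC

    frames, e_pots, e_kins, e_biases, temps = [], [], [], [], []

    def record(e_pot, e_bias, v):
        ke = kinetic(v)
        frames.append(geom.copy())
        e_pots.append(e_pot)
        e_kins.append(ke)
        e_biases.append(e_bias)
        temps.append(2.0 * ke / (dof * KB_EV))

    e_pot, e_bias, forces = eval_all(0)
    record(e_pot, e_bias, vel)
    for step in range(1, n_steps + 1):
        acc = FORCE_TO_ACC * forces / m
        vel = vel + 0.5 * timestep * acc
        geom.coordinates = geom.coordinates + 0.5 * timestep * vel
        vel = c1 * vel + c2 * rng.normal(size=vel.shape) * sigma_v
        geom.coordinates = geom.coordinates + 0.5 * timestep * vel
        e_pot, e_bias, forces = eval_all(step)
        if not (np.isfinite(e_pot) and np.all(np.isfinite(forces))):
            raise DynamicsInstability(step)
        vel = vel + 0.5 * timestep * FORCE_TO_ACC * forces / m
        if step % stride == 0:
            record(e_pot, e_bias, vel)

    return Trajectory(
        frames,
        np.array(e_pots),
        np.array(e_kins),
        np.array(e_biases),
        np.array(temps),
        timestep,
        stride,
        seed,
    )


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def nearest_heavy_neighbor(geom: Geometry, h: int) -> int:
    heavies = [i for i, e in enumerate(geom.elements) if e != "H"]
    if not heavies:
        raise ValueError("no heavy atoms in geometry")
    r = geom.coordinates
    d = [np.linalg.norm(r[i] - r[h]) for i in heavies]
    return heavies[int(np.argmin(d))]


def detect_hat(traj: Trajectory, donor: int, h: int, acceptor: int) -> HATVerdict:
    """Score a trajectory for a completed, persistent hydrogen transfer.

    Success requires the hydrogen's nearest heavy neighbor to start at
    the donor, switch to the acceptor at some frame, and stay the
    acceptor through the last frame.  ``switch_frame`` is the first frame
    of that final acceptor run.
    """
    neighbors = [nearest_heavy_neighbor(f, h) for f in traj.frames]
    final = neighbors[-1]
    if neighbors[0] != donor or final != acceptor:
        return HATVerdict(False, None, final)
    switch = len(neighbors) - 1
    while switch > 0 and neighbors[switch - 1] == acceptor:
        switch -= 1
    # every frame from `switch` on is the acceptor by construction; the
    # transfer counts only if the acceptor run reaches the end, which it
    # does here, and the start was the donor.
    return HATVerdict(True, switch, final)


def p_end(verdicts: list) -> float:
    """Fraction of replicas that ended in the transferred state."""
    if not verdicts:
        raise ValueError("no verdicts")
    return sum(v.success for v in verdicts) / len(verdicts)
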