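"""Dataset records, extended-XYZ persistence, stratified splits, statistics.

A record is one configuration (a reaction configuration or one image of an
interpolation path) with optional energy/force labels and bookkeeping:
which radical system it came from (``system_id``), the stratification tag
(``system_label``, e.g. "inter-aa+dipeptide-capped"), and its split.

The unit of split assignment is the radical system, never the single
image: all images of a path inherit their system's split, so a path can
never straddle train/val/test.  Within every stratum the per-split system
quotas follow largest-remainder rounding, which is deterministic and
independent of record order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .geometry import Geometry
from . import io as hio

SPLITS = ("train", "val", "test")


@dataclass
class DatasetRecord:
    geometry: Geometry
    system_id: str
    system_label: str
    transfer_type: str = ""
    energy: float | None = None
    forces: np.ndarray | None = None
    image_index: int | None = None
    split: str = "unassigned"

    def __post_init__(self):
        if not self.system_label:
            raise ValueError("system_label must be non-empty")


def write_dataset(records: list, path) -> None:
    frames = []
    for rec in records:
        info = {
            "system_id": rec.system_id,
            "system_label": rec.system_label,
            "transfer_type": rec.transfer_type,
            "split": rec.split,
        }
        if rec.energy is not None:
            info["energy"] = float(rec.energy)
        if rec.image_index is not None:
            info["image_index"] = int(rec.image_index)
        frames.append(hio.Frame(rec.geometry, info, rec.forces))
    hio.write_extxyz(path, frames)


def read_dataset(path) -> list:
    records = []
    for frame in hio.read_extxyz(path):
        info = dict(frame.info)
        records.append(
            DatasetRecord(
                frame.geometry,
                system_id=str(info.pop("system_id")),
                system_label=str(info.pop("system_label")),
                transfer_type=str(info.pop("transfer_type", "")),
                energy=info.pop("energy", None),
                forces=frame.forces,
                image_index=info.pop("image_index", None),
                split=str(info.pop("split", "unassigned")),
            )
        )
    return records


def _largest_remainder(n: int, fractions) -> list[int]:
    """Integer quotas summing to n, proportional to fractions."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - base[i], -i), reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_split(
    records: list,
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> list:
    """Assign train/val/test preserving the system-type distribution.

    Returns new records with ``split`` set.  Strata with fewer systems
    than active (nonzero-fraction) splits go entirely to train with a
    warning.  Deterministic under ``seed`` and invariant to record order:
    systems are keyed and sorted by id before shuffling.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three non-negative fractions (train, val, test)")
    by_label: dict = {}
    for rec in records:
        by_label.setdefault(rec.system_label, set()).add(rec.system_id)
    n_active = sum(1 for f in fractions if f > 0)
    assignment: dict = {}
    for label in sorted(by_label):
        systems = sorted(by_label[label])
        if len(systems) < n_active:
            warnings.warn(
                f"stratum {label!r} has only {len(systems)} system(s); "
                "assigning all to train"
            )
            for s in systems:
                assignment[s] = "train"
            continue
        rng = np.random.default_rng([seed, zlib.crc32(label.encode()) % (2**31)])
        order = rng.permutation(len(systems))
        quotas = _largest_remainder(len(systems), fractions)
        cursor = 0
        for split, q in zip(SPLITS, quotas):
            for k in order[cursor : cursor + q]:
                assignment[systems[k]] = split
            cursor += q
    return [replace(rec, split=assignment[rec.system_id]) for rec in records]


def dataset_stats(records: list) -> dict:
    """Counts per label/transfer type/split, atom-count and energy ranges."""
    stats = {
        "n_records": len(records),
        "n_systems": len({r.system_id for r in records}),
        "per_label": {},
        "per_transfer_type": {},
        "per_split": {},
        "atom_count_min": None,
        "atom_count_max": None,
        "energy_min": None,
        "energy_max": None,
    }
    energies = []
    for rec in records:
        stats["per_label"][rec.system_label] = (
            stats["per_label"].get(rec.system_label, 0) + 1
        )
        key = rec.transfer_type or "unknown"
        stats["per_transfer_type"][key] = stats["per_transfer_type"].get(key, 0) + 1
        stats["per_split"][rec.split] = stats["per_split"].get(rec.split, 0) + 1
        n = rec.geometry.n_atoms
        stats["atom_count_min"] = (
            n if stats["atom_count_min"] is None else min(stats["atom_count_min"], n)
        )
        stats["atom_count_max"] = (
            n if stats["atom_count_max"] is None else max(stats["atom_count_max"], n)
        )
        if rec.energy is not None:
            energies.append(rec.energy)
    if energies:
        stats["energy_min"] = float(min(energies))
        stats["energy_max"] = float(max(energies))
    if not records:
        stats["atom_count_min"] = stats["atom_count_max"] = 0
    return stats
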