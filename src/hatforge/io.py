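"""Extended-XYZ reading and writing.

Implements the standard extxyz dialect: an atom-count line, a comment line
of ``key=value`` pairs including a ``Properties=`` descriptor, then one row
per atom.  Supported per-atom columns are ``species`` (string), ``pos``
(3 reals) and ``forces`` (3 reals); frame-level keys round-trip as ints,
floats, booleans (``T``/``F``) or quoted strings.

Numeric formatting keeps round trips lossless at the tolerances the rest
of the package relies on: coordinates/forces to 1e-10 Å, energies to
relative 1e-12.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry


class ExtxyzParseError(ValueError):
    """Malformed extended-XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Frame:
    """One extended-XYZ frame: a geometry, frame metadata, optional forces."""

    geometry: Geometry
    info: dict = field(default_factory=dict)
    forces: np.ndarray | None = None


_KEYVAL = re.compile(r'(\S+?)=("[^"]*"|\S+)')


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.12e}"
    s = str(v)
    return f'"{s}"' if (" " in s or s == "") else s


def _parse_value(s: str):
    if s.startswith('"') and s.endswith('"'):
        return s[1:-1]
    if s == "T":
        return True
    if s == "F":
        return False
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def write_extxyz(path, frames) -> None:
    """Write frames (a :class:`Frame` or iterable of them) to ``path``."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(format_frame(frame))


def format_frame(frame: Frame) -> str:
    g = frame.geometry
    props = "species:S:1:pos:R:3"
    if frame.forces is not None:
        props += ":forces:R:3"
    info = dict(frame.info)
    info.setdefault("charge", g.charge)
    info.setdefault("multiplicity", g.multiplicity)
    keys = [f"Properties={props}"]
    for k, v in info.items():
        keys.append(f"{k}={_format_value(v)}")
    lines = [str(g.n_atoms), " ".join(keys)]
    for i in range(g.n_atoms):
        row = f"{g.elements[i]:<2s} " + " ".join(
            f"{x:18.10f}" for x in g.coordinates[i]
        )
        if frame.forces is not None:
            row += " " + " ".join(f"{x:18.10f}" for x in frame.forces[i])
        lines.append(row)
    return "\n".join(lines) + "\n"


def read_extxyz(path) -> list[Frame]:
    """Read all frames from an extended-XYZ file."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    frames = []
    ln = 0
    while ln < len(raw):
        if raw[ln].strip() == "" and all(l.strip() == "" for l in raw[ln:]):
            break
        try:
            n = int(raw[ln].strip())
        except ValueError:
            raise ExtxyzParseError(f"expected atom count, got {raw[ln]!r}", ln + 1)
        if ln + 1 >= len(raw):
            raise ExtxyzParseError("missing comment line", ln + 2)
        info = {k: _parse_value(v) for k, v in _KEYVAL.findall(raw[ln + 1])}
        props = info.pop("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        columns = [
            (fields[k], int(fields[k + 2])) for k in range(0, len(fields), 3)
        ]
        has_forces = any(name == "forces" for name, _ in columns)
        if ln + 2 + n > len(raw):
            raise ExtxyzParseError(
                f"frame declares {n} atoms but file ends early", ln + 1
            )
        elements, coords, forces = [], [], []
        for a in range(n):
            lineno = ln + 2 + a
            parts = raw[lineno].split()
            expected = sum(w for _, w in columns)
            if len(parts) != expected:
                raise ExtxyzParseError(
                    f"expected {expected} columns, got {len(parts)}", lineno + 1
                )
            cursor = 0
            for name, width in columns:
                chunk = parts[cursor : cursor + width]
                cursor += width
                try:
                    if name == "species":
                        elements.append(chunk[0])
                    elif name == "pos":
                        coords.append([float(x) for x in chunk])
                    elif name == "forces":
                        forces.append([float(x) for x in chunk])
                except ValueError:
                    raise ExtxyzParseError(f"bad numeric field in {name}", lineno + 1)
        charge = int(info.pop("charge", 0))
        multiplicity = int(info.pop("multiplicity", 1))
        geom = Geometry(
            elements, np.array(coords), charge=charge, multiplicity=multiplicity
        )
        frames.append(
            Frame(geom, info, np.array(forces) if has_forces else None)
        )
        ln += 2 + n
    return frames
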