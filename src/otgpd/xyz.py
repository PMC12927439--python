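"""Minimal XYZ / extended-XYZ reader and writer.

Dialect: space-separated columns, element symbol first, coordinates in
Angstrom; the comment line may carry ``energy=<float>`` and free key=value
tokens; optional per-atom force columns fx fy fz (eV/A) follow the
coordinates.  Multi-frame files concatenate frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import AtomicConfiguration

__all__ = ["Frame", "read_xyz", "write_xyz"]


@dataclass
class Frame:
    """One trajectory frame: a configuration plus optional annotations."""

    configuration: AtomicConfiguration
    energy: float | None = None
    forces: np.ndarray | None = None
    comment: dict[str, str] = field(default_factory=dict)


class XYZParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_comment(text: str) -> tuple[float | None, dict[str, str]]:
    energy = None
    extras: dict[str, str] = {}
    for token in text.split():
        if "=" in token:
            key, _, val = token.partition("=")
            if key == "energy":
                energy = float(val)
            else:
                extras[key] = val
    return energy, extras


def read_xyz(path: str | Path) -> list[Frame]:
    """Read all frames from an (extended-)XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(f"expected atom count, got {lines[i]!r}", i + 1)
        if natoms < 1:
            raise XYZParseError("atom count must be positive", i + 1)
        if i + 1 + natoms >= len(lines) + 0 and i + 1 + natoms > len(lines):
            raise XYZParseError("truncated frame", i + 1)
        energy, extras = _parse_comment(lines[i + 1] if i + 1 < len(lines) else "")
        elements: list[str] = []
        coords = np.zeros((natoms, 3))
        forces = np.zeros((natoms, 3))
        have_forces = True
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise XYZParseError("truncated frame", ln + 1)
            parts = lines[ln].split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"expected 4 or 7 columns, got {len(parts)}", ln + 1
                )
            elements.append(parts[0])
            try:
                coords[a] = [float(v) for v in parts[1:4]]
                if len(parts) == 7:
                    forces[a] = [float(v) for v in parts[4:7]]
                else:
                    have_forces = False
            except ValueError:
                raise XYZParseError(f"non-numeric field in {lines[ln]!r}", ln + 1)
        frames.append(
            Frame(
                AtomicConfiguration(tuple(elements), coords),
                energy=energy,
                forces=forces if have_forces else None,
                comment=extras,
            )
        )
        i += 2 + natoms
    return frames


def write_xyz(path: str | Path, frames: list[Frame] | Frame) -> None:
    """Write frames in the extended-XYZ dialect (lossless to ~1e-15 relative)."""
    if isinstance(frames, Frame):
        frames = [frames]
    out: list[str] = []
    for frame in frames:
        x = frame.configuration
        out.append(str(x.n_atoms))
        tokens = []
        if frame.energy is not None:
            tokens.append(f"energy={float(frame.energy)!r}")
        tokens.extend(f"{k}={v}" for k, v in frame.comment.items())
        out.append(" ".join(tokens))
        forces = frame.forces
        for a in range(x.n_atoms):
            row = f"{x.elements[a]} " + " ".join(f"{float(c)!r}" for c in x.positions[a])
            if forces is not None:
                row += " " + " ".join(
                    f"{float(c)!r}" for c in np.asarray(forces).reshape(-1, 3)[a]
                )
            out.append(row)
    Path(path).write_text("\n".join(out) + "\n")
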