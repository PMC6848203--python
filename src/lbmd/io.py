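"""Coordinate file I/O: GRO (nm, fixed columns) and XYZ (Å) formats.

All conversion between file units and the internal Å/fs system
happens here.  GRO round trips preserve coordinates to the format's
3-decimal nm precision; velocities are written when present.
"""

from __future__ import annotations

import contextlib
from typing import List, Optional, Tuple

import numpy as np

from .state import ParticleState
from .units import NM


@contextlib.contextmanager
def _open(path_or_stream, mode="r"):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        yield path_or_stream
    else:
        with open(path_or_stream, mode) as fh:
            yield fh


def write_gro(dest, state: ParticleState, names: Optional[List[str]] = None,
              title: str = "lbmd system", velocities: bool = None) -> None:
    """Write one frame in GRO format (positions nm, velocities nm/ps)."""
    n = state.n
    names = names or [str(s)[:5] for s in state.species]
    if velocities is None:
        velocities = bool(np.any(state.velocities))
    with _open(dest, "w") as fh:
        fh.write(f"{title}\n{n:5d}\n")
        for i in range(n):
            x, y, z = state.positions[i] / NM
            resid = int(state.mol_index[i]) % 100000 + 1
            line = (f"{resid:5d}{'MOL':<5s}{names[i][:5]:>5s}{(i % 100000) + 1:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}")
            if velocities:
                vx, vy, vz = state.velocities[i] / NM * 1000.0  # Å/fs → nm/ps
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        bx, by, bz = state.box / NM
        fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_gro(src) -> Tuple[ParticleState, List[str]]:
    """Read a GRO frame into a ParticleState (Å) plus atom names."""
    with _open(src) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[1])
    except (IndexError, ValueError) as exc:
        raise ValueError("line 2: expected atom count") from exc
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    names: List[str] = []
    mols = np.empty(n, dtype=int)
    has_vel = False
    for i in range(n):
        line = lines[2 + i].rstrip("\n")
        try:
            mols[i] = int(line[0:5]) - 1
            names.append(line[10:15].strip())
            pos[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line) >= 68:
                vel[i] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                has_vel = True
        except (ValueError, IndexError) as exc:
            raise ValueError(f"line {3 + i}: misaligned GRO record: {line!r}") from exc
    try:
        box = np.array([float(t) for t in lines[2 + n].split()[:3]])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"line {3 + n}: malformed box line") from exc
    state = ParticleState(pos * NM, box * NM,
                          velocities=vel * NM / 1000.0 if has_vel else None,
                          mol_index=mols)
    return state, names


class GroTrajectoryWriter:
    """Multi-frame GRO writer (concatenated frames) with a stride."""

    def __init__(self, path, names: Optional[List[str]] = None, stride: int = 1):
        self.path = path
        self.names = names
        self.stride = max(1, int(stride))
        self._count = 0
        self._fh = open(path, "w")

    def write(self, state: ParticleState, comment: str = "frame") -> None:
        self._count += 1
        if (self._count - 1) % self.stride:
            return
        write_gro(self._fh, state, names=self.names, title=comment)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class XYZTrajectoryWriter:
    """Multi-frame XYZ writer (Å) with a configurable stride."""

    def __init__(self, path, names: Optional[List[str]] = None, stride: int = 1):
        self.path = path
        self.names = names
        self.stride = max(1, int(stride))
        self._count = 0
        self._fh = open(path, "w")

    def write(self, state: ParticleState, comment: str = "") -> None:
        self._count += 1
        if (self._count - 1) % self.stride:
            return
        names = self.names or [str(s)[:4] for s in state.species]
        self._fh.write(f"{state.n}\n{comment}\n")
        for nm_, p in zip(names, state.positions):
            self._fh.write(f"{nm_:<5s} {p[0]:12.5f} {p[1]:12.5f} {p[2]:12.5f}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_xyz(src) -> Tuple[np.ndarray, List[str]]:
    """Read a (multi-frame) XYZ file: (n_frames, n_atoms, 3) in Å."""
    with _open(src) as fh:
        lines = [ln for ln in fh.readlines()]
    frames = []
    names: List[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        block = lines[i + 2:i + 2 + n]
        frame = np.empty((n, 3))
        for k, ln in enumerate(block):
            tok = ln.split()
            if len(frames) == 0:
                names.append(tok[0])
            frame[k] = [float(t) for t in tok[1:4]]
        frames.append(frame)
        i += 2 + n
    return np.array(frames), names
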