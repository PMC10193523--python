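"""Extended-XYZ trajectory reader/writer.

One frame per block: atom count, a comment line carrying the periodic cell
and step index in the conventional extxyz form

    Lattice="Lx 0 0 0 Ly 0 0 0 Lz" Properties=species:S:1:pos:R:3 step=<n>

then one ``label x y z`` line per particle.  Species labels are the package
names (solute, solvent, frozen, wall).
"""

from __future__ import annotations

import re

import numpy as np

from .engine import SPECIES, ParticleState
from .errors import ParameterError

__all__ = ["write_extxyz", "read_extxyz"]


def _comment(state: ParticleState) -> str:
    lx, ly, lz = state.box
    return (
        f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}" '
        f"Properties=species:S:1:pos:R:3 step={state.step}"
    )


def write_extxyz(path, frames, mode: str = "w") -> None:
    """Write one or more ParticleState frames to an extended-XYZ file."""
    if isinstance(frames, ParticleState):
        frames = [frames]
    with open(path, mode) as fh:
        for st in frames:
            fh.write(f"{st.n}\n{_comment(st)}\n")
            for code, (x, y, z) in zip(st.species, st.positions):
                fh.write(f"{SPECIES[code]} {x:.10g} {y:.10g} {z:.10g}\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_STEP_RE = re.compile(r"step=(\d+)")


def read_extxyz(path) -> list[ParticleState]:
    """Read all frames; velocities are not stored and come back as zeros."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            if not m:
                raise ParameterError("extxyz comment line lacks Lattice")
            cell = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
            box = np.diag(cell)
            ms = _STEP_RE.search(comment)
            step = int(ms.group(1)) if ms else 0
            pos = np.empty((n, 3))
            codes = np.empty(n, dtype=int)
            for i in range(n):
                tok = fh.readline().split()
                codes[i] = SPECIES.index(tok[0])
                pos[i] = [float(t) for t in tok[1:4]]
            frames.append(
                ParticleState(pos, np.zeros((n, 3)), codes, box, step=step)
            )
    return frames
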