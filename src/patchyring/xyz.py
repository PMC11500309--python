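"""Extended-XYZ trajectory I/O.

One frame per snapshot.  Per-atom columns: state label, position (3), and
both patch axes as extra vector columns (6).  The comment line carries the
lattice, boundary type and column properties in the conventional
``key=value`` form, so frames round-trip losslessly and remain readable by
common extended-XYZ tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .geometry import (
    Configuration,
    ParticleState,
    SimulationBox,
    STATE_FROM_INDEX,
)

__all__ = ["write_trajectory", "read_trajectory", "TrajectoryParseError"]

_PROPERTIES = "Properties=species:S:1:pos:R:3:patch1:R:3:patch2:R:3"
_LABELS = {ParticleState.ALPHA: "A", ParticleState.BETA: "B", ParticleState.GAMMA: "G"}
_STATES = {v: k for k, v in _LABELS.items()}


class TrajectoryParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def write_trajectory(frames: Iterable[Configuration], path: str | Path) -> None:
    """Write configurations as consecutive extended-XYZ frames."""
    path = Path(path)
    with open(path, "w") as fh:
        for config in frames:
            L = config.box.edges
            fh.write(f"{config.n}\n")
            fh.write(
                f'Lattice="{L[0]:.10g} 0 0 0 {L[1]:.10g} 0 0 0 {L[2]:.10g}" '
                f"{_PROPERTIES} boundary={config.box.boundary}\n"
            )
            for i in range(config.n):
                s = _LABELS[STATE_FROM_INDEX[int(config.state_indices[i])]]
                row = np.concatenate(
                    [config.positions[i], config.patch_axes[i, 0], config.patch_axes[i, 1]]
                )
                fh.write(s + " " + " ".join(f"{v:.17g}" for v in row) + "\n")


def read_trajectory(path: str | Path) -> list[Configuration]:
    """Read extended-XYZ frames written by :func:`write_trajectory`.

    Raises :class:`TrajectoryParseError` with the offending line number on
    malformed or truncated input (never a silent partial read).
    """
    path = Path(path)
    frames: list[Configuration] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise TrajectoryParseError("expected atom count", k + 1)
        if k + 1 >= len(lines):
            raise TrajectoryParseError("missing comment line", k + 2)
        comment = lines[k + 1]
        edges = _parse_lattice(comment, k + 2)
        boundary = "periodic" if "boundary=periodic" in comment else "reflective"
        if k + 2 + n > len(lines):
            raise TrajectoryParseError(
                f"truncated frame: expected {n} atom lines", len(lines)
            )
        pos = np.empty((n, 3))
        axes = np.empty((n, 2, 3))
        states = []
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if len(parts) != 10:
                raise TrajectoryParseError(
                    f"expected 10 columns, got {len(parts)}", k + 3 + i
                )
            if parts[0] not in _STATES:
                raise TrajectoryParseError(f"unknown species {parts[0]!r}", k + 3 + i)
            states.append(_STATES[parts[0]])
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError:
                raise TrajectoryParseError("non-numeric coordinate", k + 3 + i)
            pos[i] = vals[0:3]
            axes[i, 0] = vals[3:6]
            axes[i, 1] = vals[6:9]
        box = SimulationBox(tuple(edges), boundary)
        frames.append(Configuration(pos, axes, states, box))
        k += 2 + n
    return frames


def _parse_lattice(comment: str, lineno: int) -> tuple[float, float, float]:
    key = 'Lattice="'
    start = comment.find(key)
    if start < 0:
        raise TrajectoryParseError("missing Lattice", lineno)
    end = comment.find('"', start + len(key))
    if end < 0:
        raise TrajectoryParseError("unterminated Lattice", lineno)
    vals = [float(v) for v in comment[start + len(key):end].split()]
    if len(vals) != 9:
        raise TrajectoryParseError("Lattice needs 9 values", lineno)
    return (vals[0], vals[4], vals[8])
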