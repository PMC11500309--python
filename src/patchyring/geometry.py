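"""Domain geometry: particles, boxes, configurations, and ring targets.

Particles are spherical beads decorated with two surface patches.  A patch is
represented by a unit vector (the "patch axis") from the bead center to the
patch center.  The angle between a particle's two patch axes is fixed to the
interior angle of the target polygon, so that a closed ring of ``n`` particles
with every patch pointing at its ring neighbour is geometrically consistent.

Distances follow the box convention: plain Euclidean differences inside a
reflective box, minimum-image differences under periodic boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ParticleState",
    "Particle",
    "SimulationBox",
    "Configuration",
    "TargetStructure",
    "GeometryError",
    "PackingError",
    "interior_angle",
    "make_ring_target",
    "random_configuration",
    "pair_vector",
]

# canonical state labels; MD / large systems use ALPHA only
class ParticleState(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"
    GAMMA = "gamma"


STATE_INDEX = {ParticleState.ALPHA: 0, ParticleState.BETA: 1, ParticleState.GAMMA: 2}
STATE_FROM_INDEX = {v: k for k, v in STATE_INDEX.items()}


class GeometryError(ValueError):
    """Raised when a requested construction is geometrically impossible."""


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place all particles."""


def interior_angle(n: int) -> float:
    """Interior angle of a regular ``n``-gon, radians: (n-2)*pi/n.

    This is the fixed angle between the two patch axes of every particle in
    an ``n``-ring target (2.356, 2.513, 2.658 rad for n = 8, 10, 13).
    """
    if n < 3:
        raise GeometryError(f"ring target needs n >= 3 vertices, got {n}")
    return (n - 2) * math.pi / n


@dataclass
class Particle:
    """One patchy particle: bead position, two patch axes, internal state."""

    position: np.ndarray  # (3,), Angstrom
    patch_axes: np.ndarray  # (2, 3), unit vectors
    state: ParticleState

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.patch_axes = np.asarray(self.patch_axes, dtype=float)
        norms = np.linalg.norm(self.patch_axes, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("patch axes must be unit vectors")


@dataclass(frozen=True)
class SimulationBox:
    """Rectangular simulation cell with reflective or periodic walls."""

    edges: tuple[float, float, float]
    boundary: str = "reflective"  # or "periodic"

    def __post_init__(self) -> None:
        if self.boundary not in ("reflective", "periodic"):
            raise ValueError(f"unknown boundary type {self.boundary!r}")
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))

    @classmethod
    def cubic(cls, edge: float, boundary: str = "reflective") -> "SimulationBox":
        return cls((edge, edge, edge), boundary)

    @property
    def periodic(self) -> bool:
        return self.boundary == "periodic"

    @property
    def edge_array(self) -> np.ndarray:
        return np.asarray(self.edges, dtype=float)


class Configuration:
    """Ordered collection of particles in a box; the geometric ground truth.

    Internally stored as flat arrays (positions ``(n,3)``, patch axes
    ``(n,2,3)``, state indices ``(n,)``) so that the compiled engines can use
    them without conversion.
    """

    def __init__(
        self,
        positions: np.ndarray,
        patch_axes: np.ndarray,
        states: Sequence[ParticleState] | np.ndarray,
        box: SimulationBox,
    ) -> None:
        self.positions = np.array(positions, dtype=float)
        self.patch_axes = np.array(patch_axes, dtype=float)
        if isinstance(states, np.ndarray) and states.dtype != object:
            self.state_indices = states.astype(np.int64)
        else:
            self.state_indices = np.array([STATE_INDEX[s] for s in states], dtype=np.int64)
        self.box = box
        n = len(self.positions)
        if self.patch_axes.shape != (n, 2, 3) or self.state_indices.shape != (n,):
            raise ValueError("inconsistent configuration array shapes")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def states(self) -> list[ParticleState]:
        return [STATE_FROM_INDEX[int(i)] for i in self.state_indices]

    def particle(self, i: int) -> Particle:
        return Particle(self.positions[i].copy(), self.patch_axes[i].copy(),
                        STATE_FROM_INDEX[int(self.state_indices[i])])

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.patch_axes.copy(),
                             self.state_indices.copy(), self.box)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Configuration):
            return NotImplemented
        return (
            self.box == other.box
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.patch_axes, other.patch_axes)
            and np.array_equal(self.state_indices, other.state_indices)
        )


def pair_vector(config: Configuration, i: int, j: int) -> tuple[np.ndarray, float]:
    """Separation vector r_ij (from i to j) and its norm.

    Reflective boxes use the plain Euclidean difference; periodic boxes the
    minimum-image convention.  Antisymmetric: r_ij = -r_ji.
    """
    if i == j:
        raise IndexError("pair_vector requires two distinct particles")
    d = config.positions[j] - config.positions[i]
    if config.box.periodic:
        L = config.box.edge_array
        d -= L * np.round(d / L)
    return d, float(np.linalg.norm(d))


@dataclass
class TargetStructure:
    """Labeled ring adjacency: which (particle, patch) pairs are neighbours.

    ``adjacency`` holds quadruples (i, a, j, b): patch ``a`` of particle ``i``
    bonds patch ``b`` of particle ``j``.  Each quadruple is stored once with
    i < j; the set forms a single n-cycle over particles.
    """

    n: int
    adjacency: frozenset[tuple[int, int, int, int]]
    reference: Configuration = field(repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for (i, a, j, b) in self.adjacency:
            for key in ((i, a), (j, b)):
                if key in seen:
                    raise ValueError(f"patch {key} appears in more than one target bond")
                seen.add(key)
        if len(self.adjacency) != self.n:
            raise ValueError("ring target must have exactly n bonds")

    @property
    def n_bonds(self) -> int:
        return len(self.adjacency)

    def partner_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n,2) arrays: target partner particle / partner patch per patch."""
        pj = np.full((self.n, 2), -1, dtype=np.int64)
        pb = np.full((self.n, 2), -1, dtype=np.int64)
        for (i, a, j, b) in self.adjacency:
            pj[i, a], pb[i, a] = j, b
            pj[j, b], pb[j, b] = i, a
        return pj, pb

    def to_json(self) -> str:
        return json.dumps(
            {"n": self.n, "adjacency": sorted(self.adjacency)}, indent=1
        )

    @classmethod
    def from_json(cls, text: str, reference: Configuration) -> "TargetStructure":
        d = json.loads(text)
        adj = frozenset(tuple(q) for q in d["adjacency"])
        return cls(d["n"], adj, reference)


def _ring_states(n: int, pattern: str) -> list[ParticleState]:
    A, B, G = ParticleState.ALPHA, ParticleState.BETA, ParticleState.GAMMA
    if pattern == "single":
        return [A] * n
    if pattern == "alternating":
        if n % 2:
            raise GeometryError(
                f"strict alpha/beta alternation needs an even ring, got n={n}"
            )
        return [A if k % 2 == 0 else B for k in range(n)]
    if pattern == "three-state":
        # gamma sits between the two ends of the alternating 12-path; its
        # neighbours are one alpha and one beta (both attractive to gamma)
        return [G] + [A if k % 2 == 0 else B for k in range(n - 1)]
    raise ValueError(f"unknown state pattern {pattern!r}")


def default_state_pattern(n: int) -> str:
    return "three-state" if n % 2 else "alternating"


def make_ring_target(
    n: int,
    box: SimulationBox,
    state_pattern: str | None = None,
    sigma_bead: float = 2.0,
) -> tuple[Configuration, TargetStructure]:
    """Build the reference n-ring and its labeled adjacency.

    Beads sit on a circle in the box midplane at the spacing that minimises
    the bead-bead Lennard-Jones energy (2^(1/6)*sigma), so the reference
    configuration is a local energy minimum.  Every particle's two patch axes
    point exactly at its two ring neighbours, which fixes the inter-axis angle
    to the polygon interior angle (n-2)*pi/n.
    """
    angle = interior_angle(n)  # validates n
    if state_pattern is None:
        state_pattern = default_state_pattern(n)
    states = _ring_states(n, state_pattern)

    spacing = 2.0 ** (1.0 / 6.0) * sigma_bead
    radius = spacing / (2.0 * math.sin(math.pi / n))
    half = min(box.edges) / 2.0
    # wall clearance on bead centers; sigma/4 is the largest uniform margin
    # compatible with the published cells (the 10-ring sits 0.87 A off the
    # 9 A box walls at the LJ-minimum bond length)
    if radius + sigma_bead / 4.0 > half:
        raise GeometryError(
            f"{n}-ring of radius {radius:.2f} A does not fit in box "
            f"{min(box.edges):.2f} A with {sigma_bead / 4:.2f} A wall clearance"
        )

    center = box.edge_array / 2.0
    phis = 2.0 * math.pi * np.arange(n) / n
    positions = center + radius * np.stack(
        [np.cos(phis), np.sin(phis), np.zeros(n)], axis=1
    )

    axes = np.empty((n, 2, 3))
    for k in range(n):
        for a, nb in enumerate(((k - 1) % n, (k + 1) % n)):
            v = positions[nb] - positions[k]
            axes[k, a] = v / np.linalg.norm(v)

    config = Configuration(positions, axes, states, box)
    # patch 1 of k (towards k+1) meets patch 0 of k+1 (towards k)
    adjacency = frozenset(
        (k, 1, (k + 1) % n, 0) if k < (k + 1) % n else ((k + 1) % n, 0, k, 1)
        for k in range(n)
    )
    target = TargetStructure(n, adjacency, config)

    assert abs(float(np.dot(axes[0, 0], axes[0, 1])) - math.cos(angle)) < 1e-9
    return config, target


def _random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _quat_rotation_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def reference_patch_axes(angle: float) -> np.ndarray:
    """Body-frame patch axes, symmetric about x in the xy-plane."""
    h = angle / 2.0
    return np.array(
        [[math.cos(h), math.sin(h), 0.0], [math.cos(h), -math.sin(h), 0.0]]
    )


def random_configuration(
    n: int,
    box: SimulationBox,
    min_separation: float = 2.0,
    seed: int = 0,
    patch_angle: float | None = None,
    states: Sequence[ParticleState] | None = None,
    max_retries: int = 10_000,
) -> Configuration:
    """Random non-overlapping initial configuration.

    Bead centers are drawn uniformly in the box and rejected until all pair
    distances (box convention) are >= ``min_separation``; orientations are
    uniformly random rigid rotations of the reference two-patch geometry.
    Deterministic for a fixed seed.
    """
    if patch_angle is None:
        # fewer than 3 particles cannot themselves define a polygon; the
        # 2-particle experiments use the 10-ring patch geometry
        patch_angle = interior_angle(n) if n >= 3 else interior_angle(10)
    if states is None:
        if n % 2 == 0:
            states = _ring_states(n, "alternating")
        elif n == 13:
            states = _ring_states(n, "three-state")
        else:
            states = _ring_states(n, "single")

    rng = np.random.default_rng(seed)
    ref = reference_patch_axes(patch_angle)
    L = box.edge_array
    positions = np.empty((n, 3))
    placed = 0
    tries = 0
    while placed < n:
        if tries > max_retries * max(n, 1):
            raise PackingError(
                f"could not place {n} particles with min separation "
                f"{min_separation} A in box {box.edges} after {tries} tries"
            )
        tries += 1
        cand = rng.uniform(0.0, 1.0, size=3) * L
        ok = True
        for k in range(placed):
            d = cand - positions[k]
            if box.periodic:
                d -= L * np.round(d / L)
            if float(np.dot(d, d)) < min_separation**2:
                ok = False
                break
        if ok:
            positions[placed] = cand
            placed += 1

    axes = np.empty((n, 2, 3))
    for k in range(n):
        R = _quat_rotation_matrix(_random_unit_quaternion(rng))
        axes[k] = ref @ R.T

    return Configuration(positions, axes, list(states), box)


def cycle_adjacency_target(config: Configuration) -> TargetStructure:
    """Nominal n-cycle adjacency over an arbitrary configuration.

    Used for bond counting in systems without a geometric reference target
    (e.g. the 100-particle periodic runs, where the drive acts on any bond
    and the observable is the bond count): supplies the n-bond normalization
    and a labeling, with the given configuration as reference.
    """
    n = config.n
    adjacency = frozenset(
        (k, 1, k + 1, 0) if k + 1 < n else (0, 0, k, 1) for k in range(n)
    )
    return TargetStructure(n, adjacency, config)
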