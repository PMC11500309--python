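"""Interaction potentials.

Two families are provided, matching the two engines:

* Monte Carlo: Lennard-Jones bead repulsion/attraction (truncated at r_c)
  plus a Kern-Frenkel patch term -- a square well in the bead-bead distance
  gated by an angular criterion on both patch orientations.
* Molecular dynamics: a pseudo-hard-sphere (PHS) bead -- the steep
  cut-and-shifted Mie (50, 49) potential of Jover et al., which approximates
  a hard sphere while remaining differentiable -- plus a continuous
  square-well (CSW) attraction between patch *sites*, a tanh-smoothed well
  in the patch-patch distance.  A periodic square wave can modulate the CSW
  well depth in time, which is the nonequilibrium drive for MD.

All energies are kJ/mol, distances Angstrom, times ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Configuration, pair_vector

__all__ = [
    "KB",
    "InteractionParams",
    "SquareWaveDrive",
    "lj_bead",
    "angular_gate",
    "kf_patch_energy",
    "phs_bead",
    "phs_bead_force",
    "csw_patch",
    "csw_patch_force",
    "square_wave",
    "effective_patch_depth",
    "total_particle_energy",
    "total_system_energy",
    "check_single_bond_condition",
    "patch_depth_matrix",
]

#: Boltzmann constant, kJ/mol/K
KB = 0.0083145


def patch_depth_matrix(eps_patch: float, n_states: int = 2) -> np.ndarray:
    """Symmetric state-pair well-depth matrix.

    Same-state patches never interact (U^aa = U^bb = U^gg = 0); all
    cross-state pairs share the depth ``eps_patch``.  ``n_states=1`` is the
    single-state MD convention where every patch pair attracts.
    """
    if n_states == 1:
        return np.array([[eps_patch]], dtype=float)
    m = np.full((n_states, n_states), eps_patch, dtype=float)
    np.fill_diagonal(m, 0.0)
    return m


@dataclass
class InteractionParams:
    """All interaction constants for both engines.

    Defaults are the published system: eps_bead = 0.75 kJ/mol and
    sigma_bead = 2 A for the LJ bead with 5 A cutoff; patch half-width
    theta_max = 0.35 rad; Kern-Frenkel well width delta = 0.9 A (largest
    round value satisfying the single-bond inequality at theta_max = 0.35);
    PHS exponents (50, 49) with eps_r = 0.24 kJ/mol; CSW well radius
    r_w = 0.12*sigma and steepness eta = 0.005*sigma.
    """

    eps_bead: float = 0.75
    sigma_bead: float = 2.0
    r_cut: float = 5.0
    theta_max: float = 0.35
    delta: float = 0.9
    patch_depth: np.ndarray = field(
        default_factory=lambda: patch_depth_matrix(10.0)
    )
    lambda_a: float = 49.0
    lambda_r: float = 50.0
    eps_r: float = 0.24
    r_w: float | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        if self.r_w is None:
            self.r_w = 0.12 * self.sigma_bead
        if self.eta is None:
            self.eta = 0.005 * self.sigma_bead
        self.patch_depth = np.asarray(self.patch_depth, dtype=float)
        if np.any(self.patch_depth < 0):
            raise ValueError("patch well depths must be non-negative")
        if not np.allclose(self.patch_depth, self.patch_depth.T):
            raise ValueError("patch depth matrix must be symmetric")
        if self.lambda_r <= self.lambda_a:
            raise ValueError("PHS requires lambda_r > lambda_a")
        if not check_single_bond_condition(self):
            raise ValueError(
                "single-bond condition sin(theta_max) <= (sigma/2)/(sigma+delta) "
                f"violated: sin({self.theta_max}) = {math.sin(self.theta_max):.4f} > "
                f"{(self.sigma_bead / 2) / (self.sigma_bead + self.delta):.4f}"
            )

    @property
    def eps_patch(self) -> float:
        """Largest cross-state well depth (the scalar eps_patch of a run)."""
        return float(self.patch_depth.max())

    def with_depth(self, eps_patch: float, n_states: int | None = None) -> "InteractionParams":
        ns = n_states if n_states is not None else len(self.patch_depth)
        return InteractionParams(
            eps_bead=self.eps_bead, sigma_bead=self.sigma_bead, r_cut=self.r_cut,
            theta_max=self.theta_max, delta=self.delta,
            patch_depth=patch_depth_matrix(eps_patch, ns),
            lambda_a=self.lambda_a, lambda_r=self.lambda_r, eps_r=self.eps_r,
            r_w=self.r_w, eta=self.eta,
        )


def check_single_bond_condition(params: InteractionParams) -> bool:
    """Geometric guarantee that a patch can hold at most one bond.

    sin(theta_max) <= (sigma_bead/2) / (sigma_bead + delta): two partners
    cannot both sit inside one patch cone within the well range.
    """
    return math.sin(params.theta_max) <= (params.sigma_bead / 2.0) / (
        params.sigma_bead + params.delta
    )


@dataclass
class SquareWaveDrive:
    """Periodic square-wave modulation of the patch well depth.

    Symmetric about the baseline: +amplitude for the first half-period
    ("high" phase, deeper well), -amplitude for the second.  The time
    average over a full period is zero.
    """

    amplitude: float
    period: float = 20.0  # ps

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("drive period must be positive")

    def phase(self, t: float) -> str:
        return "high" if (t % self.period) < self.period / 2.0 else "low"


def square_wave(t: float, drive: SquareWaveDrive) -> float:
    """Instantaneous offset U_square(t): +A or -A."""
    return drive.amplitude if (t % drive.period) < drive.period / 2.0 else -drive.amplitude


def effective_patch_depth(t: float, baseline: float, drive: SquareWaveDrive | None) -> float:
    """Time-dependent well depth eps_patch + U_square(t).

    May be negative during the low phase (transiently repulsive patches);
    no clamping is applied.
    """
    if drive is None:
        return baseline
    return baseline + square_wave(t, drive)


# ---------------------------------------------------------------- MC family

def lj_bead(r: float, params: InteractionParams) -> float:
    """Truncated 12-6 Lennard-Jones bead-bead energy (no shift)."""
    if r <= 0:
        raise ValueError("bead separation must be positive")
    if r >= params.r_cut:
        return 0.0
    s6 = (params.sigma_bead / r) ** 6
    return 4.0 * params.eps_bead * (s6 * s6 - s6)


def angular_gate(
    r_ij: np.ndarray, n_i: np.ndarray, n_j: np.ndarray, theta_max: float
) -> int:
    """Kern-Frenkel angular criterion, 1 if both patches face each other.

    Requires r_hat_ij . n_i >= cos(theta_max) and r_hat_ji . n_j >=
    cos(theta_max) (boundary inclusive).
    """
    r = np.linalg.norm(r_ij)
    if r == 0.0:
        raise ValueError("coincident particles have no orientation gate")
    c = math.cos(theta_max)
    rhat = r_ij / r
    if float(np.dot(rhat, n_i)) >= c and float(np.dot(-rhat, n_j)) >= c:
        return 1
    return 0


def kf_patch_energy(
    config: Configuration,
    i: int,
    j: int,
    patch_pair: tuple[int, int],
    params: InteractionParams,
) -> float:
    """Kern-Frenkel square-well energy of one patch pair.

    -depth(state_i, state_j) when sigma <= r_ij < sigma + delta and the
    angular gate is open; 0 otherwise.  Exactly two-valued.
    """
    a, b = patch_pair
    depth = params.patch_depth[config.state_indices[i], config.state_indices[j]]
    if depth == 0.0:
        return 0.0
    d, r = pair_vector(config, i, j)
    if not (params.sigma_bead <= r < params.sigma_bead + params.delta):
        return 0.0
    if angular_gate(d, config.patch_axes[i, a], config.patch_axes[j, b], params.theta_max):
        return -float(depth)
    return 0.0


# ---------------------------------------------------------------- MD family

def _phs_prefactor(params: InteractionParams) -> float:
    lr, la = params.lambda_r, params.lambda_a
    return lr * (lr / la) ** la * params.eps_r


def phs_bead(r: float, params: InteractionParams) -> float:
    """Pseudo-hard-sphere (cut-and-shifted Mie 50-49) bead energy.

    Purely repulsive: lr*(lr/la)^la * eps_r * [(s/r)^lr - (s/r)^la] + eps_r
    for r < (lr/la)*sigma, zero beyond; continuous at the cutoff.
    """
    if r <= 0:
        raise ValueError("bead separation must be positive")
    lr, la = params.lambda_r, params.lambda_a
    rc = (lr / la) * params.sigma_bead
    if r >= rc:
        return 0.0
    s = params.sigma_bead / r
    return _phs_prefactor(params) * (s**lr - s**la) + params.eps_r


def phs_bead_force(r: float, params: InteractionParams) -> float:
    """-dU/dr of the PHS bead potential (radial force, >0 repulsive)."""
    lr, la = params.lambda_r, params.lambda_a
    rc = (lr / la) * params.sigma_bead
    if r <= 0:
        raise ValueError("bead separation must be positive")
    if r >= rc:
        return 0.0
    s = params.sigma_bead / r
    return _phs_prefactor(params) * (lr * s**lr - la * s**la) / r


def csw_patch(r: float, depth: float, params: InteractionParams) -> float:
    """Continuous square-well patch-site attraction.

    -(depth/2) * [1 - tanh((r - r_w)/eta)]: a smooth well of depth ``depth``
    and radius r_w, with edge steepness eta.  ``r`` is the distance between
    the centers of two patches (not bead centers).
    """
    return -0.5 * depth * (1.0 - math.tanh((r - params.r_w) / params.eta))


def csw_patch_force(r: float, depth: float, params: InteractionParams) -> float:
    """-dU/dr of the CSW patch potential (negative = attractive pull)."""
    c = math.cosh((r - params.r_w) / params.eta)
    return -0.5 * depth / (params.eta * c * c)


# ---------------------------------------------------------------- assembly

def total_particle_energy(
    config: Configuration,
    i: int,
    params: InteractionParams,
    mode: str = "mc",
    t: float | None = None,
    drive: SquareWaveDrive | None = None,
) -> float:
    """Total interaction energy of particle ``i`` with all partners.

    ``mode='mc'``: LJ bead + Kern-Frenkel patches.  ``mode='md'``: PHS bead
    + CSW patch sites, with the square wave (if any) modulating the well
    depth at time ``t``.
    """
    u = 0.0
    for j in range(config.n):
        if j == i:
            continue
        d, r = pair_vector(config, i, j)
        if mode == "mc":
            u += lj_bead(r, params)
            for a in range(2):
                for b in range(2):
                    u += kf_patch_energy(config, i, j, (a, b), params)
        elif mode == "md":
            u += phs_bead(r, params)
            base = float(
                params.patch_depth[config.state_indices[i], config.state_indices[j]]
            )
            depth = effective_patch_depth(0.0 if t is None else t, base, drive)
            half = params.sigma_bead / 2.0
            for a in range(2):
                for b in range(2):
                    site_i = config.positions[i] + half * config.patch_axes[i, a]
                    site_j = config.positions[j] + half * config.patch_axes[j, b]
                    dv = site_j - site_i
                    if config.box.periodic:
                        L = config.box.edge_array
                        dv -= L * np.round(dv / L)
                    u += csw_patch(float(np.linalg.norm(dv)), depth, params)
        else:
            raise ValueError(f"unknown energy mode {mode!r}")
    return u


def total_system_energy(
    config: Configuration,
    params: InteractionParams,
    mode: str = "mc",
    t: float | None = None,
    drive: SquareWaveDrive | None = None,
) -> float:
    """Total energy = half the sum of per-particle energies."""
    return 0.5 * sum(
        total_particle_energy(config, i, params, mode, t, drive)
        for i in range(config.n)
    )
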