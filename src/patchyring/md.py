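"""Reduced-fidelity rigid-body molecular dynamics engine.

Particles are rigid bodies: a 10 amu bead at the body origin plus two 1 amu
patch sites at sigma/2 along the patch axes (the sites supply the entire
rotational inertia).  Beads repel through the pseudo-hard-sphere Mie
(50, 49) potential; patch sites attract through the continuous square well,
optionally modulated by a periodic square wave -- the MD analogue of the
bond-promoting MC drive.  Integration is velocity Verlet with quaternion
orientation propagation, thermostatted by a single Nose-Hoover chain
coupled to the total kinetic energy.

Defaults follow the published protocol: dt = 0.2 fs, T = 40 K, trajectory
stride 100 fs, single internal state (all patches attract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._md_kernel import MECH, run_md_kernel
from .geometry import Configuration, TargetStructure, reference_patch_axes
from .observables import BondEvent, ObservableSeries
from .potentials import KB, InteractionParams, SquareWaveDrive

__all__ = [
    "MDParams",
    "RigidBodyState",
    "DivergenceError",
    "body_inertia",
    "initialize_bodies",
    "compute_forces",
    "velocity_verlet_step",
    "nose_hoover_step",
    "run_md",
    "two_particle_experiment",
]

BEAD_MASS = 10.0  # amu
SITE_MASS = 1.0  # amu
TOTAL_MASS = BEAD_MASS + 2.0 * SITE_MASS


@dataclass(frozen=True)
class MDParams:
    """MD run parameters (dt in fs, duration in ps, stride in fs)."""

    dt: float = 0.2
    temperature: float = 40.0
    damping_time: float = 0.1  # ps, Nose-Hoover relaxation
    stride: float = 100.0
    duration: float = 100.0
    seed: int = 0
    thermostat: bool = True
    bond_scale: float = 2.0  # bond cutoff = r_w + bond_scale * eta

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt * 1e-3:
            raise ValueError("need dt > 0 and duration >= dt")

    @property
    def dt_ps(self) -> float:
        return self.dt * 1e-3

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt_ps))

    @property
    def stride_steps(self) -> int:
        return max(1, int(round(self.stride / self.dt)))

    @property
    def kT(self) -> float:
        return KB * self.temperature


@dataclass
class RigidBodyState:
    """Full phase-space state of the rigid bodies."""

    positions: np.ndarray  # (n, 3)
    velocities: np.ndarray  # (n, 3), A/ps
    quaternions: np.ndarray  # (n, 4) unit
    omegas: np.ndarray  # (n, 3), body frame, rad/ps
    box_edges: np.ndarray
    periodic: bool
    patch_angle: float

    def copy(self) -> "RigidBodyState":
        return RigidBodyState(
            self.positions.copy(), self.velocities.copy(),
            self.quaternions.copy(), self.omegas.copy(),
            self.box_edges.copy(), self.periodic, self.patch_angle,
        )


class DivergenceError(RuntimeError):
    """Integration produced non-finite coordinates or energies."""


def body_inertia(patch_angle: float, sigma_bead: float = 2.0) -> np.ndarray:
    """Principal moments (amu A^2) of the two patch sites at sigma/2.

    Body frame places the patch axes in the xy-plane symmetric about x;
    the bead at the origin contributes nothing.
    """
    half = patch_angle / 2.0
    d = sigma_bead / 2.0
    s2 = math.sin(half) ** 2
    c2 = math.cos(half) ** 2
    return np.array([
        2.0 * SITE_MASS * d * d * s2,
        2.0 * SITE_MASS * d * d * c2,
        2.0 * SITE_MASS * d * d,
    ])


def _quat_from_axes(patch_axes: np.ndarray, patch_angle: float) -> np.ndarray:
    """Unit quaternion rotating the body-frame patch axes onto given axes."""
    ref = reference_patch_axes(patch_angle)
    # orthonormal frames built identically from each pair of axes
    def frame(ax):
        e1 = ax[0] + ax[1]
        e1 /= np.linalg.norm(e1)
        e3 = np.cross(ax[0], ax[1])
        n3 = np.linalg.norm(e3)
        e3 = e3 / n3
        e2 = np.cross(e3, e1)
        return np.stack([e1, e2, e3], axis=1)

    R = frame(patch_axes) @ frame(ref).T
    # rotation matrix -> quaternion (Shepperd)
    tr = np.trace(R)
    if tr > 0:
        w = math.sqrt(1.0 + tr) / 2.0
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:
        k = int(np.argmax(np.diag(R)))
        i, j = (k + 1) % 3, (k + 2) % 3
        s = math.sqrt(1.0 + R[k, k] - R[i, i] - R[j, j]) * 2.0
        q = np.empty(4)
        q[k + 1] = s / 4.0
        q[i + 1] = (R[i, k] + R[k, i]) / s
        q[j + 1] = (R[j, k] + R[k, j]) / s
        q[0] = (R[j, i] - R[i, j]) / s
        w, x, y, z = q
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def initialize_bodies(
    config: Configuration,
    params: MDParams,
    patch_angle: float,
    interactions: InteractionParams,
) -> RigidBodyState:
    """Rigid-body state from a Configuration with Maxwell-Boltzmann
    velocities at params.temperature (seeded); net momentum removed."""
    n = config.n
    rng = np.random.default_rng(params.seed)
    kT = params.kT
    v_std = math.sqrt(MECH * kT / TOTAL_MASS)
    vel = rng.normal(0.0, v_std, size=(n, 3))
    vel -= vel.mean(axis=0)
    I = body_inertia(patch_angle, interactions.sigma_bead)
    omega = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(MECH * kT / I)
    quat = np.stack(
        [_quat_from_axes(config.patch_axes[i], patch_angle) for i in range(n)]
    )
    return RigidBodyState(
        config.positions.copy(), vel, quat, omega,
        config.box.edge_array.copy(), config.box.periodic, patch_angle,
    )


def compute_forces(
    state: RigidBodyState,
    interactions: InteractionParams,
    t: float = 0.0,
    drive: SquareWaveDrive | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-body force (kJ/mol/A) and torque (kJ/mol), plus total potential.

    PHS bead-bead forces act on the body origins; CSW patch-site forces
    (with the drive-modulated depth at time ``t``) act on the patch sites
    and are mapped to origin force + torque.  Pair forces are antisymmetric
    (Newton's third law).
    """
    from ._md_kernel import _md_forces
    from .potentials import effective_patch_depth

    n = len(state.positions)
    forces = np.empty((n, 3))
    torques = np.empty((n, 3))
    sites = np.empty((n, 2, 3))
    body_sites = reference_patch_axes(state.patch_angle) * (
        interactions.sigma_bead / 2.0
    )
    depth = effective_patch_depth(t, float(interactions.patch_depth.max()), drive)
    u = _md_forces(
        state.positions, state.quaternions, body_sites, depth,
        interactions.sigma_bead, interactions.lambda_a, interactions.lambda_r,
        interactions.eps_r, interactions.r_w, interactions.eta,
        state.box_edges, state.periodic, forces, torques, sites,
    )
    return forces, torques, float(u)


def _single_step(state, params, interactions, drive, thermostat):
    series, out, _ = run_md(
        state, None,
        MDParams(dt=params.dt, temperature=params.temperature,
                 damping_time=params.damping_time, stride=params.dt,
                 duration=params.dt_ps, seed=params.seed,
                 thermostat=thermostat),
        interactions, drive,
    )
    return out


def velocity_verlet_step(
    state: RigidBodyState,
    params: MDParams,
    interactions: InteractionParams,
    drive: SquareWaveDrive | None = None,
) -> RigidBodyState:
    """One NVE velocity-Verlet step (translation + quaternion rotation)."""
    return _single_step(state, params, interactions, drive, thermostat=False)


def nose_hoover_step(
    state: RigidBodyState,
    params: MDParams,
    interactions: InteractionParams,
    drive: SquareWaveDrive | None = None,
) -> RigidBodyState:
    """One thermostatted step (Nose-Hoover on total kinetic energy)."""
    return _single_step(state, params, interactions, drive, thermostat=True)


_PHASE_NAMES = {0: "none", 1: "high", 2: "low"}


def run_md(
    initial: Configuration | RigidBodyState,
    target: TargetStructure | None,
    params: MDParams,
    interactions: InteractionParams,
    drive: SquareWaveDrive | None = None,
    stop_at_assembly: bool = False,
    stop_at_break: bool = False,
    max_events: int = 200_000,
):
    """Integrate and return (ObservableSeries, RigidBodyState, diagnostics).

    The series carries R (fraction of target bonds, counted from patch-site
    distances), total potential energy, the magnitude of the force on
    particle 0, the kinetic temperature, and the bond formation/breakage
    events tagged with the drive phase.  ``diagnostics`` reports the
    maximum drift of the conserved (extended) energy.
    """
    if isinstance(initial, Configuration):
        angle = math.acos(
            float(np.clip(np.dot(initial.patch_axes[0, 0], initial.patch_axes[0, 1]), -1, 1))
        )
        state = initialize_bodies(initial, params, angle, interactions)
    else:
        state = initial.copy()
    n = len(state.positions)
    n_target = target.n_bonds if target is not None else max(n, 1)

    depth = float(interactions.patch_depth.max())
    amplitude = drive.amplitude if drive is not None else 0.0
    period = drive.period if drive is not None else 20.0
    Ibody = body_inertia(state.patch_angle, interactions.sigma_bead)
    body_sites = reference_patch_axes(state.patch_angle) * (interactions.sigma_bead / 2.0)
    g_dof = 6 * n - 3 if n > 1 else 6
    Q = g_dof * params.kT * params.damping_time**2
    r_bond = interactions.r_w + params.bond_scale * interactions.eta

    n_steps = params.n_steps
    stride = params.stride_steps
    cap = n_steps // stride + 3
    rec_t = np.empty(cap)
    rec_R = np.empty(cap)
    rec_U = np.empty(cap)
    rec_F = np.empty(cap)
    rec_T = np.empty(cap)
    ev_t = np.empty(max_events)
    ev_kind = np.empty(max_events, dtype=np.int8)
    ev_pair = np.empty((max_events, 4), dtype=np.int64)
    ev_phase = np.empty(max_events, dtype=np.int8)

    (n_rec, n_ev, first_full, first_break, drift, err) = run_md_kernel(
        state.positions, state.velocities, state.quaternions, state.omegas,
        body_sites, Ibody, TOTAL_MASS,
        depth, interactions.sigma_bead,
        interactions.lambda_a, interactions.lambda_r, interactions.eps_r,
        interactions.r_w, interactions.eta,
        state.box_edges, state.periodic,
        amplitude, period,
        params.dt_ps, n_steps, params.kT, params.thermostat, Q, g_dof,
        stride, r_bond, n_target,
        stop_at_assembly, stop_at_break,
        rec_t, rec_R, rec_U, rec_F, rec_T,
        ev_t, ev_kind, ev_pair, ev_phase,
    )
    if err:
        raise DivergenceError("non-finite energy during MD integration")

    events = [
        BondEvent(
            time=float(ev_t[k]),
            kind="formation" if ev_kind[k] else "breakage",
            pair=(int(ev_pair[k, 0]), int(ev_pair[k, 1]),
                  int(ev_pair[k, 2]), int(ev_pair[k, 3])),
            phase=_PHASE_NAMES[int(ev_phase[k])],
        )
        for k in range(n_ev)
    ]
    series = ObservableSeries(
        time=rec_t[:n_rec].copy(),
        R=rec_R[:n_rec].copy(),
        S=np.zeros(n_rec),
        U=rec_U[:n_rec].copy(),
        time_unit="ps",
        cap=params.duration,
        first_assembly_step=float(first_full) if first_full >= 0 else -1,
        first_break_step=float(first_break) if first_break >= 0 else -1,
        bond_events=events,
    )
    diagnostics = {
        "conserved_drift": float(drift),
        "force_trace": rec_F[:n_rec].copy(),
        "kinetic_temperature": rec_T[:n_rec].copy(),
        "first_assembly_ps": float(first_full),
        "first_break_ps": float(first_break),
    }
    return series, state, diagnostics


def two_particle_experiment(
    eps_patch: float,
    drive: SquareWaveDrive | None = None,
    seed: int = 0,
    duration: float = 2000.0,
    interactions: InteractionParams | None = None,
    params: MDParams | None = None,
):
    """Two particles in a 2 x 6 x 6 A periodic cell, run to the first bond.

    Returns a dict with the potential-energy trace, the inter-particle
    force-magnitude trace, the first-bond time (ps, NaN if none within the
    duration cap), and the recorded times.
    """
    from .geometry import SimulationBox, interior_angle, random_configuration

    if interactions is None:
        interactions = InteractionParams(
            patch_depth=np.array([[eps_patch]]), theta_max=0.35, delta=0.9
        )
    else:
        interactions = interactions.with_depth(eps_patch, 1)
    if params is None:
        params = MDParams(duration=duration, seed=seed)
    box = SimulationBox((2.0, 6.0, 6.0), "periodic")
    config = random_configuration(
        2, box, min_separation=interactions.sigma_bead, seed=seed,
        patch_angle=interior_angle(10),
        states=None,
    )
    # single-state particles: both attract
    config.state_indices[:] = 0
    series, state, diag = run_md(
        config, None, params, interactions, drive=drive,
        stop_at_assembly=False, stop_at_break=False,
    )
    # first bond = first frame with any patch pair inside the well
    bond_frames = np.nonzero(series.R > 0)[0]
    t_bond = float(series.time[bond_frames[0]]) if len(bond_frames) else math.nan
    return {
        "time": series.time,
        "potential": series.U,
        "force": diag["force_trace"],
        "first_bond_ps": t_bond,
        "series": series,
    }
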