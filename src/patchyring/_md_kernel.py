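"""Numba-compiled rigid-body MD inner loop.

Each patchy particle is one rigid body: a bead (10 amu) at the body origin
and two patch sites (1 amu each) at sigma/2 along the body-frame patch
axes.  Bead-bead forces are pseudo-hard-sphere (Mie 50-49 cut-and-shifted);
patch-site forces are the continuous square well, whose depth may be
modulated in time by a square wave (the nonequilibrium drive).  Site forces
are mapped to a net force on the body origin plus a torque.

Integration is velocity Verlet for translation and body-frame angular
velocity with exact quaternion propagation per step, optionally coupled to
a single Nose-Hoover thermostat acting on the full (translational +
rotational) kinetic energy.

Units: Angstrom, ps, amu, kJ/mol.  MECH = 100 converts kJ/mol/A / amu to
A/ps^2 (1 kJ/mol = 0.01 amu A^2/ps^2).
"""

import math

import numpy as np
from numba import njit

MECH = 100.0  # (kJ/mol/A)/amu -> A/ps^2
FORCE_CLAMP = 1.0e4  # kJ/mol/A, pair-force cap at pathological overlaps


@njit(cache=True)
def _quat_to_matrix(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def _site_positions(pos, quat, body_sites, sites):
    """World-frame patch-site positions, sites shape (n, 2, 3)."""
    n = pos.shape[0]
    R = np.empty((3, 3))
    for i in range(n):
        _quat_to_matrix(quat[i], R)
        for a in range(2):
            for k in range(3):
                sites[i, a, k] = pos[i, k] + (
                    R[k, 0] * body_sites[a, 0]
                    + R[k, 1] * body_sites[a, 1]
                    + R[k, 2] * body_sites[a, 2]
                )


@njit(cache=True)
def _md_forces(pos, quat, body_sites, depth_eff, sigma,
               lambda_a, lambda_r, eps_r, r_w, eta,
               L, periodic, forces, torques, sites):
    """Fill forces/torques (world frame, kJ/mol/A and kJ/mol); return U."""
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            forces[i, k] = 0.0
            torques[i, k] = 0.0
    _site_positions(pos, quat, body_sites, sites)
    u = 0.0
    phs_rc = (lambda_r / lambda_a) * sigma
    phs_rc2 = phs_rc * phs_rc
    phs_pref = lambda_r * (lambda_r / lambda_a) ** lambda_a * eps_r
    csw_cut = r_w + 25.0 * eta  # tanh tail < 2e-22 beyond: negligible
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            sx = 0.0
            sy = 0.0
            sz = 0.0
            if periodic:
                sx = -L[0] * math.floor(dx / L[0] + 0.5)
                sy = -L[1] * math.floor(dy / L[1] + 0.5)
                sz = -L[2] * math.floor(dz / L[2] + 0.5)
                dx += sx
                dy += sy
                dz += sz
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < phs_rc2:
                r = math.sqrt(r2)
                s = sigma / r
                sla = s ** lambda_a
                slr = sla * s
                u += phs_pref * (slr - sla) + eps_r
                fmag = phs_pref * (lambda_r * slr - lambda_a * sla) / r
                if fmag > FORCE_CLAMP:
                    fmag = FORCE_CLAMP
                # repulsive: push i away from j (force on i along -r_ij)
                fx = -fmag * dx / r
                fy = -fmag * dy / r
                fz = -fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
            d = depth_eff
            # patch-site pairs; same periodic shift as the bead pair
            for a in range(2):
                for b in range(2):
                    px = sites[j, b, 0] + sx - sites[i, a, 0]
                    py = sites[j, b, 1] + sy - sites[i, a, 1]
                    pz = sites[j, b, 2] + sz - sites[i, a, 2]
                    pr2 = px * px + py * py + pz * pz
                    pr = math.sqrt(pr2)
                    if pr > csw_cut or pr < 1e-12:
                        continue
                    th = math.tanh((pr - r_w) / eta)
                    u += -0.5 * d * (1.0 - th)
                    sech2 = 1.0 - th * th
                    # F_i = -dU/ds_i = (dU/dp) p_hat, p_hat from i to j:
                    # a positive depth pulls the sites together
                    dudr = 0.5 * d * sech2 / eta
                    fx = dudr * px / pr
                    fy = dudr * py / pr
                    fz = dudr * pz / pr
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
                    # torque about each body origin from its site force
                    rix = sites[i, a, 0] - pos[i, 0]
                    riy = sites[i, a, 1] - pos[i, 1]
                    riz = sites[i, a, 2] - pos[i, 2]
                    torques[i, 0] += riy * fz - riz * fy
                    torques[i, 1] += riz * fx - rix * fz
                    torques[i, 2] += rix * fy - riy * fx
                    rjx = sites[j, b, 0] - pos[j, 0]
                    rjy = sites[j, b, 1] - pos[j, 1]
                    rjz = sites[j, b, 2] - pos[j, 2]
                    torques[j, 0] += rjy * (-fz) - rjz * (-fy)
                    torques[j, 1] += rjz * (-fx) - rjx * (-fz)
                    torques[j, 2] += rjx * (-fy) - rjy * (-fx)
    return u


@njit(cache=True)
def _kinetic_energy(vel, omega, mass, Ibody):
    """Total kinetic energy, kJ/mol (0.01 * 1/2 m v^2 in amu, A/ps)."""
    n = vel.shape[0]
    k = 0.0
    for i in range(n):
        k += mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        k += (Ibody[0] * omega[i, 0] ** 2 + Ibody[1] * omega[i, 1] ** 2
              + Ibody[2] * omega[i, 2] ** 2)
    return 0.5 * k / MECH


@njit(cache=True)
def _rotate_quat(q, omega, dt):
    """Propagate q by body-frame angular velocity omega over dt (exact for
    constant omega), then renormalize."""
    wx, wy, wz = omega[0], omega[1], omega[2]
    wn = math.sqrt(wx * wx + wy * wy + wz * wz)
    if wn < 1e-14:
        return
    half = 0.5 * wn * dt
    c = math.cos(half)
    s = math.sin(half) / wn
    dw, dx, dy, dz = c, s * wx, s * wy, s * wz
    w0, x0, y0, z0 = q[0], q[1], q[2], q[3]
    # q_new = q * dq (body-frame composition)
    q[0] = w0 * dw - x0 * dx - y0 * dy - z0 * dz
    q[1] = w0 * dx + x0 * dw + y0 * dz - z0 * dy
    q[2] = w0 * dy - x0 * dz + y0 * dw + z0 * dx
    q[3] = w0 * dz + x0 * dy - y0 * dx + z0 * dw
    norm = math.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
    q[0] /= norm
    q[1] /= norm
    q[2] /= norm
    q[3] /= norm


@njit(cache=True)
def _body_torque_accel(q, torque_w, omega, Ibody, out):
    """Angular acceleration in body frame: I^-1 (tau_b*MECH - w x I w)."""
    R = np.empty((3, 3))
    _quat_to_matrix(q, R)
    # tau_b = R^T tau_w
    tbx = R[0, 0] * torque_w[0] + R[1, 0] * torque_w[1] + R[2, 0] * torque_w[2]
    tby = R[0, 1] * torque_w[0] + R[1, 1] * torque_w[1] + R[2, 1] * torque_w[2]
    tbz = R[0, 2] * torque_w[0] + R[1, 2] * torque_w[1] + R[2, 2] * torque_w[2]
    lx = Ibody[0] * omega[0]
    ly = Ibody[1] * omega[1]
    lz = Ibody[2] * omega[2]
    gx = omega[1] * lz - omega[2] * ly
    gy = omega[2] * lx - omega[0] * lz
    gz = omega[0] * ly - omega[1] * lx
    out[0] = (tbx * MECH - gx) / Ibody[0]
    out[1] = (tby * MECH - gy) / Ibody[1]
    out[2] = (tbz * MECH - gz) / Ibody[2]


@njit(cache=True)
def _count_bonds(sites, L, periodic, r_bond, pairs_out):
    """Bond indicators over all patch-site pairs; returns bond count.

    pairs_out is an int8 array of shape (n, 2, n, 2) holding the current
    bond map (i, a, j, b) for i < j.
    """
    n = sites.shape[0]
    count = 0
    rb2 = r_bond * r_bond
    for i in range(n):
        for a in range(2):
            for j in range(i + 1, n):
                for b in range(2):
                    px = sites[j, b, 0] - sites[i, a, 0]
                    py = sites[j, b, 1] - sites[i, a, 1]
                    pz = sites[j, b, 2] - sites[i, a, 2]
                    if periodic:
                        px -= L[0] * math.floor(px / L[0] + 0.5)
                        py -= L[1] * math.floor(py / L[1] + 0.5)
                        pz -= L[2] * math.floor(pz / L[2] + 0.5)
                    bonded = px * px + py * py + pz * pz < rb2
                    pairs_out[i, a, j, b] = 1 if bonded else 0
                    if bonded:
                        count += 1
    return count


@njit(cache=True)
def run_md_kernel(pos, vel, quat, omega, body_sites, Ibody, mass,
                  depth_base, sigma, lambda_a, lambda_r, eps_r, r_w, eta,
                  L, periodic,
                  amplitude, period,
                  dt, n_steps, kT, thermostat, Q, g_dof,
                  rec_stride, r_bond, n_target_bonds,
                  stop_at_full, stop_at_break,
                  rec_t, rec_R, rec_U, rec_F, rec_T,
                  ev_t, ev_kind, ev_pair, ev_phase):
    """Integrate n_steps of rigid-body dynamics in place.

    Observables (time ps, R, potential energy, |force on particle 0|,
    kinetic temperature) are recorded every rec_stride steps; bond
    formation/breakage events are detected at the same stride and appended
    to the ev_* arrays.  Returns (n_rec, n_events, first_full_t,
    first_break_t, nh_conserved_drift, err).
    """
    n = pos.shape[0]
    forces = np.empty((n, 3))
    torques = np.empty((n, 3))
    sites = np.empty((n, 2, 3))
    wdot = np.empty(3)
    bonds = np.zeros((n, 2, n, 2), np.int8)
    bonds_prev = np.zeros((n, 2, n, 2), np.int8)

    xi = 0.0
    eta_nh = 0.0
    err = 0
    first_full = -1.0
    first_break = -1.0
    n_rec = 0
    n_ev = 0
    max_ev = ev_t.shape[0]

    def _depth(t):
        if amplitude == 0.0:
            return depth_base
        if (t % period) < 0.5 * period:
            return depth_base + amplitude
        return depth_base - amplitude

    t = 0.0
    u = _md_forces(pos, quat, body_sites, _depth(t), sigma,
                   lambda_a, lambda_r, eps_r, r_w, eta,
                   L, periodic, forces, torques, sites)
    count = _count_bonds(sites, L, periodic, r_bond, bonds_prev)
    ke = _kinetic_energy(vel, omega, mass, Ibody)
    e0 = u + ke
    nh_drift = 0.0

    rec_t[0] = 0.0
    rec_R[0] = count / n_target_bonds
    rec_U[0] = u
    rec_F[0] = math.sqrt(forces[0, 0] ** 2 + forces[0, 1] ** 2 + forces[0, 2] ** 2)
    rec_T[0] = 2.0 * ke / (g_dof * 0.0083145)
    n_rec = 1
    if count >= n_target_bonds:
        first_full = 0.0

    for step in range(1, n_steps + 1):
        # half kick (with NH friction if on)
        for i in range(n):
            for k in range(3):
                vel[i, k] += 0.5 * dt * (MECH * forces[i, k] / mass - xi * vel[i, k])
            _body_torque_accel(quat[i], torques[i], omega[i], Ibody, wdot)
            for k in range(3):
                omega[i, k] += 0.5 * dt * (wdot[k] - xi * omega[i, k])
        # drift
        for i in range(n):
            for k in range(3):
                pos[i, k] += dt * vel[i, k]
                if periodic:
                    pos[i, k] -= L[k] * math.floor(pos[i, k] / L[k])
            _rotate_quat(quat[i], omega[i], dt)
        t = step * dt
        u = _md_forces(pos, quat, body_sites, _depth(t), sigma,
                       lambda_a, lambda_r, eps_r, r_w, eta,
                       L, periodic, forces, torques, sites)
        # thermostat variable update on mid-step kinetic energy
        if thermostat:
            ke = _kinetic_energy(vel, omega, mass, Ibody)
            xi += dt * (2.0 * ke - g_dof * kT) / Q
            eta_nh += dt * xi
        # second half kick
        for i in range(n):
            for k in range(3):
                vel[i, k] = (vel[i, k] + 0.5 * dt * MECH * forces[i, k] / mass) / (
                    1.0 + 0.5 * dt * xi
                )
            _body_torque_accel(quat[i], torques[i], omega[i], Ibody, wdot)
            for k in range(3):
                omega[i, k] = (omega[i, k] + 0.5 * dt * wdot[k]) / (
                    1.0 + 0.5 * dt * xi
                )
        # divergence guard
        if not math.isfinite(u):
            err = 1
            break

        if step % rec_stride == 0:
            ke = _kinetic_energy(vel, omega, mass, Ibody)
            count = _count_bonds(sites, L, periodic, r_bond, bonds)
            phase = 0  # none
            if amplitude != 0.0:
                phase = 1 if (t % period) < 0.5 * period else 2
            for i in range(n):
                for a in range(2):
                    for j in range(i + 1, n):
                        for b in range(2):
                            now = bonds[i, a, j, b]
                            was = bonds_prev[i, a, j, b]
                            if now != was and n_ev < max_ev:
                                ev_t[n_ev] = t
                                ev_kind[n_ev] = 1 if now else 0
                                ev_pair[n_ev, 0] = i
                                ev_pair[n_ev, 1] = a
                                ev_pair[n_ev, 2] = j
                                ev_pair[n_ev, 3] = b
                                ev_phase[n_ev] = phase
                                n_ev += 1
                            bonds_prev[i, a, j, b] = now
            rec_t[n_rec] = t
            rec_R[n_rec] = count / n_target_bonds
            rec_U[n_rec] = u
            rec_F[n_rec] = math.sqrt(
                forces[0, 0] ** 2 + forces[0, 1] ** 2 + forces[0, 2] ** 2
            )
            rec_T[n_rec] = 2.0 * ke / (g_dof * 0.0083145)
            n_rec += 1
            if first_full < 0.0 and count >= n_target_bonds:
                first_full = t
            if first_break < 0.0 and count < n_target_bonds:
                first_break = t
            if thermostat:
                cons = u + ke + 0.5 * Q * xi * xi + g_dof * kT * eta_nh
                drift = abs(cons - e0)
                if drift > nh_drift:
                    nh_drift = drift
            else:
                drift = abs(u + ke - e0)
                if drift > nh_drift:
                    nh_drift = drift
            if stop_at_full and first_full >= 0.0:
                break
            if stop_at_break and first_break >= 0.0:
                break

    return n_rec, n_ev, first_full, first_break, nh_drift, err
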