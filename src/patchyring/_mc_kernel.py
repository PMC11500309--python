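"""Numba-compiled Metropolis Monte Carlo inner loop.

The kernel operates on flat arrays (positions, patch axes, state indices)
and implements single-particle translation/rotation moves, the Kern-Frenkel
bond bookkeeping, and the bond-promoting nonequilibrium acceptance rule:
moves that form target-adjacent bonds gain a bias -eps_drive in the
exponent, moves that break them gain +eps_drive, and moves that leave the
target bond set unchanged follow plain Metropolis.

A pair-energy cache (E[i, j] = full interaction energy of pair ij) makes
each proposal cost a single O(n) scan: the old particle energy is the row
sum of the cache, the new one comes from the scan, and accepted moves write
the scanned pair energies back.  The cache is validated against a full
recomputation at checkpoints.

Entropy production is accumulated per accepted move as the log-ratio of the
forward and reverse acceptance probabilities, which for a symmetric
proposal evaluates to -(dU - bias)/kT.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline='always')
def _rng_next(rs):
    """xorshift128+ step on the 2-word uint64 state; returns a uint64."""
    x = rs[0]
    y = rs[1]
    rs[0] = y
    x ^= x << np.uint64(23)
    rs[1] = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    return rs[1] + y


@njit(cache=True, inline='always')
def _rng_uniform(rs):
    """Uniform double in [0, 1) from the top 53 bits."""
    return (_rng_next(rs) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _rng_seed(seed):
    """SplitMix64 expansion of a small seed into the xorshift state."""
    rs = np.empty(2, np.uint64)
    z = np.uint64(seed)
    for k in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rs[k] = w ^ (w >> np.uint64(31))
    if rs[0] == 0 and rs[1] == 0:
        rs[0] = np.uint64(0x1234567890ABCDEF)
    return rs


@njit(cache=True, inline='always')
def _is_target_bond(labeled, tgt_j, tgt_b, i, a, j, b):
    if not labeled:
        return True
    return tgt_j[i, a] == j and tgt_b[i, a] == b


@njit(cache=True, fastmath=True, inline='always')
def _particle_scan(pos, axes, states, i, xi, yi, zi, ax_i,
                   L, periodic, depth,
                   four_eps, sigma2, rc2, bead_phs,
                   phs_pref, phs_rc2, lambda_a, eps_r,
                   cos_tmax, well_hi2, pj_out, pb_out, pair_e):
    """Energy of particle i at candidate coordinates.

    Fills ``pair_e`` (length n) with per-partner pair energies and
    ``pj_out``/``pb_out`` (length 2) with the bonded partner particle and
    patch per patch of i (-1 if free).  Returns the total.
    """
    n = pos.shape[0]
    u = 0.0
    pj_out[0] = -1
    pj_out[1] = -1
    pb_out[0] = -1
    pb_out[1] = -1
    si = states[i]
    for j in range(n):
        if j == i:
            pair_e[j] = 0.0
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        dz = pos[j, 2] - zi
        if periodic:
            dx -= L[0] * math.floor(dx / L[0] + 0.5)
            dy -= L[1] * math.floor(dy / L[1] + 0.5)
            dz -= L[2] * math.floor(dz / L[2] + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        upair = 0.0
        if bead_phs:
            if r2 < phs_rc2:
                s2 = sigma2 / r2
                s = math.sqrt(s2)
                sla = s ** lambda_a
                upair = phs_pref * (sla * s - sla) + eps_r
        else:
            if r2 < rc2:
                s2 = sigma2 / r2
                s6 = s2 * s2 * s2
                upair = four_eps * (s6 * s6 - s6)
        d = depth[si, states[j]]
        if d > 0.0 and sigma2 <= r2 < well_hi2:
            inv_r = 1.0 / math.sqrt(r2)
            rhx = dx * inv_r
            rhy = dy * inv_r
            rhz = dz * inv_r
            for a in range(2):
                ci = rhx * ax_i[a, 0] + rhy * ax_i[a, 1] + rhz * ax_i[a, 2]
                if ci >= cos_tmax:
                    for b in range(2):
                        cj = -(rhx * axes[j, b, 0] + rhy * axes[j, b, 1]
                               + rhz * axes[j, b, 2])
                        if cj >= cos_tmax:
                            upair -= d
                            pj_out[a] = j
                            pb_out[a] = b
        pair_e[j] = upair
        u += upair
    return u


@njit(cache=True)
def _full_scan(pos, axes, states, L, periodic, depth,
               four_eps, sigma2, rc2, bead_phs,
               phs_pref, phs_rc2, lambda_a, eps_r,
               cos_tmax, well_hi2,
               labeled, tgt_j, tgt_b, bond_j, bond_b, E):
    """Rebuild the pair-energy cache and bond arrays from scratch.

    Returns (U_total, target_bond_count).
    """
    n = pos.shape[0]
    u = 0.0
    pj = np.empty(2, np.int64)
    pb = np.empty(2, np.int64)
    pair_e = np.empty(n)
    for i in range(n):
        u += _particle_scan(pos, axes, states, i,
                            pos[i, 0], pos[i, 1], pos[i, 2], axes[i],
                            L, periodic, depth, four_eps, sigma2, rc2,
                            bead_phs, phs_pref, phs_rc2, lambda_a, eps_r,
                            cos_tmax, well_hi2, pj, pb, pair_e)
        for j in range(n):
            E[i, j] = pair_e[j]
        bond_j[i, 0] = pj[0]
        bond_j[i, 1] = pj[1]
        bond_b[i, 0] = pb[0]
        bond_b[i, 1] = pb[1]
    tcount = 0
    for i in range(n):
        for a in range(2):
            j = bond_j[i, a]
            if j > i and _is_target_bond(labeled, tgt_j, tgt_b, i, a, j, bond_b[i, a]):
                tcount += 1
    return 0.5 * u, tcount


@njit(cache=True, fastmath=True)
def run_mc_kernel(pos, axes, states, L, periodic,
                  depth, eps_bead, sigma, r_cut, bead_phs,
                  lambda_a, lambda_r, eps_r,
                  cos_tmax, delta,
                  kT, max_trans, max_rot, p_trans,
                  eps_drive, labeled, tgt_j, tgt_b, n_target_bonds,
                  n_steps, stride, seed,
                  stop_at_full, stop_at_break, check_interval,
                  rec_step, rec_R, rec_S, rec_U):
    """Run n_steps single-particle MC moves in place.

    Returns (U, S, target_count, first_full, first_break, accepts, n_rec,
    err).  ``err`` = 1 if the incremental energy cache drifted beyond 1e-8
    kJ/mol from a full recomputation at a checkpoint.
    """
    rs = _rng_seed(seed)
    n = pos.shape[0]
    four_eps = 4.0 * eps_bead
    sigma2 = sigma * sigma
    rc2 = r_cut * r_cut
    phs_rc = (lambda_r / lambda_a) * sigma
    phs_rc2 = phs_rc * phs_rc
    phs_pref = lambda_r * (lambda_r / lambda_a) ** lambda_a * eps_r
    well_hi = sigma + delta
    well_hi2 = well_hi * well_hi

    bond_j = -np.ones((n, 2), np.int64)
    bond_b = -np.ones((n, 2), np.int64)
    E = np.zeros((n, n))
    U, tcount = _full_scan(pos, axes, states, L, periodic, depth,
                           four_eps, sigma2, rc2, bead_phs,
                           phs_pref, phs_rc2, lambda_a, eps_r,
                           cos_tmax, well_hi2,
                           labeled, tgt_j, tgt_b, bond_j, bond_b, E)
    S = 0.0
    first_full = -1
    first_break = -1
    if tcount >= n_target_bonds:
        first_full = 0
    accepts = 0
    n_rec = 0
    rec_step[n_rec] = 0
    rec_R[n_rec] = tcount / n_target_bonds
    rec_S[n_rec] = 0.0
    rec_U[n_rec] = U
    n_rec += 1

    pjn = np.empty(2, np.int64)
    pbn = np.empty(2, np.int64)
    pair_new = np.empty(n)
    cand_ax = np.empty((2, 3))
    err = 0
    until_rec = stride
    until_check = check_interval

    for step in range(1, n_steps + 1):
        i = int(_rng_uniform(rs) * n)
        is_trans = _rng_uniform(rs) < p_trans
        nx = pos[i, 0]
        ny = pos[i, 1]
        nz = pos[i, 2]
        rejected = False
        if is_trans:
            nx += (2.0 * _rng_uniform(rs) - 1.0) * max_trans
            ny += (2.0 * _rng_uniform(rs) - 1.0) * max_trans
            nz += (2.0 * _rng_uniform(rs) - 1.0) * max_trans
            for a in range(2):
                cand_ax[a, 0] = axes[i, a, 0]
                cand_ax[a, 1] = axes[i, a, 1]
                cand_ax[a, 2] = axes[i, a, 2]
            if periodic:
                nx -= L[0] * math.floor(nx / L[0])
                ny -= L[1] * math.floor(ny / L[1])
                nz -= L[2] * math.floor(nz / L[2])
            elif (nx <= 0.0 or nx >= L[0] or ny <= 0.0 or ny >= L[1]
                    or nz <= 0.0 or nz >= L[2]):
                # reflective walls: hard rejection outside the box
                rejected = True
        else:
            # rigid rotation of the patch frame: uniform axis, uniform angle
            uz = 2.0 * _rng_uniform(rs) - 1.0
            phi = 2.0 * math.pi * _rng_uniform(rs)
            rho = math.sqrt(max(1.0 - uz * uz, 0.0))
            ux = rho * math.cos(phi)
            uy = rho * math.sin(phi)
            ang = (2.0 * _rng_uniform(rs) - 1.0) * max_rot
            ca = math.cos(ang)
            sa = math.sin(ang)
            for a in range(2):
                vx = axes[i, a, 0]
                vy = axes[i, a, 1]
                vz = axes[i, a, 2]
                dotuv = ux * vx + uy * vy + uz * vz
                cx = uy * vz - uz * vy
                cy = uz * vx - ux * vz
                cz = ux * vy - uy * vx
                cand_ax[a, 0] = vx * ca + cx * sa + ux * dotuv * (1.0 - ca)
                cand_ax[a, 1] = vy * ca + cy * sa + uy * dotuv * (1.0 - ca)
                cand_ax[a, 2] = vz * ca + cz * sa + uz * dotuv * (1.0 - ca)

        if not rejected:
            u_old = 0.0
            for j in range(n):
                u_old += E[i, j]
            u_new = _particle_scan(pos, axes, states, i, nx, ny, nz, cand_ax,
                                   L, periodic, depth, four_eps, sigma2, rc2,
                                   bead_phs, phs_pref, phs_rc2, lambda_a,
                                   eps_r, cos_tmax, well_hi2,
                                   pjn, pbn, pair_new)
            forms = 0
            breaks = 0
            for a in range(2):
                jo = bond_j[i, a]
                bo = bond_b[i, a]
                jn = pjn[a]
                bn = pbn[a]
                if jo == jn and bo == bn:
                    continue
                if jo >= 0 and _is_target_bond(labeled, tgt_j, tgt_b, i, a, jo, bo):
                    breaks += 1
                if jn >= 0 and _is_target_bond(labeled, tgt_j, tgt_b, i, a, jn, bn):
                    forms += 1
            bias = (forms - breaks) * eps_drive
            dU = u_new - u_old
            arg = -(dU - bias) / kT
            if arg >= 0.0 or _rng_uniform(rs) < math.exp(arg):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                for a in range(2):
                    axes[i, a, 0] = cand_ax[a, 0]
                    axes[i, a, 1] = cand_ax[a, 1]
                    axes[i, a, 2] = cand_ax[a, 2]
                for j in range(n):
                    E[i, j] = pair_new[j]
                    E[j, i] = pair_new[j]
                U += dU
                S += arg  # log-ratio of forward/reverse acceptance probs
                accepts += 1
                for a in range(2):
                    jo = bond_j[i, a]
                    bo = bond_b[i, a]
                    jn = pjn[a]
                    bn = pbn[a]
                    if jo == jn and bo == bn:
                        continue
                    if jo >= 0:
                        bond_j[jo, bo] = -1
                        bond_b[jo, bo] = -1
                    if jn >= 0:
                        ko = bond_j[jn, bn]
                        if ko >= 0 and ko != i:
                            # stale partner: excluded by the single-bond
                            # geometry; clear defensively
                            co = bond_b[jn, bn]
                            bond_j[ko, co] = -1
                            bond_b[ko, co] = -1
                            if _is_target_bond(labeled, tgt_j, tgt_b, jn, bn, ko, co):
                                tcount -= 1
                        bond_j[jn, bn] = i
                        bond_b[jn, bn] = a
                    bond_j[i, a] = jn
                    bond_b[i, a] = bn
                tcount += forms - breaks
                if first_full < 0 and tcount >= n_target_bonds:
                    first_full = step
                if first_break < 0 and tcount < n_target_bonds:
                    first_break = step
                if (stop_at_full and first_full >= 0) or \
                   (stop_at_break and first_break >= 0):
                    rec_step[n_rec] = step
                    rec_R[n_rec] = tcount / n_target_bonds
                    rec_S[n_rec] = S
                    rec_U[n_rec] = U
                    n_rec += 1
                    break
        until_rec -= 1
        if until_rec == 0:
            until_rec = stride
            rec_step[n_rec] = step
            rec_R[n_rec] = tcount / n_target_bonds
            rec_S[n_rec] = S
            rec_U[n_rec] = U
            n_rec += 1
        until_check -= 1
        if until_check == 0:
            until_check = check_interval
            bj2 = -np.ones((n, 2), np.int64)
            bb2 = -np.ones((n, 2), np.int64)
            E2 = np.zeros((n, n))
            U2, tc2 = _full_scan(pos, axes, states, L, periodic, depth,
                                 four_eps, sigma2, rc2, bead_phs,
                                 phs_pref, phs_rc2, lambda_a, eps_r,
                                 cos_tmax, well_hi2,
                                 labeled, tgt_j, tgt_b, bj2, bb2, E2)
            if abs(U - U2) > 1e-8:
                err = 1
                break
            U = U2
            tcount = tc2
            bond_j = bj2
            bond_b = bb2
            E = E2

    return U, S, tcount, first_full, first_break, accepts, n_rec, err
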