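"""Numba kernels for force/energy evaluation and Langevin integration.

All kernels operate on packed float64/int32 arrays prepared by
:mod:`ringmotor.energetics`.  Energy conventions:

* bonds/angles/restraints: harmonic, zero at reference.
* excluded volume: ``eps * ((sigma/r)^12 - 1)`` for ``r < sigma``, else 0
  (purely repulsive, continuous at contact).
* electrostatics: Debye-Hueckel, truncated and shifted at ``r_cut``.
* base pairing: Morse well ``D * ((1 - exp(-a (r - r0)))^2 - 1)``.
* stacking / nucleosome sites / factor wells: Gaussian wells
  ``-eps * exp(-(r - r0)^2 / (2 sigma^2))``.
* motor hydrogen-bond wells: the same Gaussian evaluated against the
  nearest eligible phosphate of each pore loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, fastmath=False)


@njit(**NB_OPTS)
def bond_forces(pos, bonds, k, r0, f):
    e = 0.0
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[m]
        e += 0.5 * k[m] * dr * dr
        if r > 1e-12:
            g = -k[m] * dr / r
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def angle_forces(pos, angles, k, t0, f):
    e = 0.0
    for m in range(angles.shape[0]):
        i = angles[m, 0]
        j = angles[m, 1]
        l = angles[m, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[l, 0] - pos[j, 0]
        by = pos[l, 1] - pos[j, 1]
        bz = pos[l, 2] - pos[j, 2]
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        ct = (ax * bx + ay * by + az * bz) / (la * lb)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        th = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        dth = th - t0[m]
        e += 0.5 * k[m] * dth * dth
        dedth = k[m] * dth
        # d(theta)/d(ri) = (ct * a_hat - b_hat) / (la * st)
        c1 = dedth / (la * st)
        c2 = dedth / (lb * st)
        fix = -c1 * (ct * ax / la - bx / lb)
        fiy = -c1 * (ct * ay / la - by / lb)
        fiz = -c1 * (ct * az / la - bz / lb)
        flx = -c2 * (ct * bx / lb - ax / la)
        fly = -c2 * (ct * by / lb - ay / la)
        flz = -c2 * (ct * bz / lb - az / la)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[l, 0] += flx
        f[l, 1] += fly
        f[l, 2] += flz
        f[j, 0] -= fix + flx
        f[j, 1] -= fiy + fly
        f[j, 2] -= fiz + flz
    return e


@njit(**NB_OPTS)
def restraint_forces(pos, idx, k, target, f):
    e = 0.0
    for m in range(idx.shape[0]):
        i = idx[m]
        dx = pos[i, 0] - target[m, 0]
        dy = pos[i, 1] - target[m, 1]
        dz = pos[i, 2] - target[m, 2]
        e += 0.5 * k[m] * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= k[m] * dx
        f[i, 1] -= k[m] * dy
        f[i, 2] -= k[m] * dz
    return e


@njit(**NB_OPTS)
def build_pairs(pos, sub, cutoff, group, chain, resix, excl_sep, out_i, out_j):
    """Half pair list over the bead subset ``sub`` within ``cutoff``.

    Pairs in the same exclusion group (group >= 0), pairs close along
    one chain (same chain, bead-index separation <= excl_sep), and pairs
    involving a nonbonded-silent bead (group == -2, the pore-loop grip
    beads) are skipped.  Returns the number of pairs written (or -1 on
    overflow).
    """
    n = sub.shape[0]
    c2 = cutoff * cutoff
    m = 0
    cap = out_i.shape[0]
    for a in range(n):
        i = sub[a]
        if group[i] == -2:
            continue
        for bix in range(a + 1, n):
            j = sub[bix]
            if group[j] == -2:
                continue
            if group[i] == group[j] and group[i] >= 0:
                continue
            if chain[i] == chain[j]:
                d = i - j
                if d < 0:
                    d = -d
                if d <= excl_sep:
                    continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < c2:
                if m >= cap:
                    return -1
                out_i[m] = i
                out_j[m] = j
                m += 1
    return m


@njit(**NB_OPTS)
def ev_forces(pos, radius, pi, pj, npairs, eps, partner, f):
    """Purely repulsive excluded volume on a pair list.

    Harmonic overlap repulsion ``0.5 * eps * (sigma - r)^2`` for
    ``r < sigma = r_i + r_j``; zero beyond contact and of bounded curvature
    (a hard-wall power law is linearly unstable at the adopted timestep).
    ``partner[i]`` is the base-pairing partner of bead ``i`` (or -1): such
    pairs are excluded here because their interaction is the Morse term.
    """
    e = 0.0
    for m in range(npairs):
        i = pi[m]
        j = pj[m]
        if partner[i] == j:
            continue
        sig = radius[i] + radius[j]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= sig * sig or r2 < 1e-20:
            continue
        r = np.sqrt(r2)
        ov = sig - r
        e += 0.5 * eps * ov * ov
        g = eps * ov / r  # = -dU/dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def elec_forces(pos, q_intra, q_cross, is_dna, pi, pj, npairs, lb, kappa,
                rcut, f):
    e = 0.0
    shift = np.exp(-kappa * rcut) / rcut
    for m in range(npairs):
        i = pi[m]
        j = pj[m]
        if is_dna[i] == 1 and is_dna[j] == 1:
            qq = q_intra[i] * q_intra[j]
        else:
            qq = q_cross[i] * q_cross[j]
        if qq == 0.0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rcut * rcut or r2 < 1e-20:
            continue
        r = np.sqrt(r2)
        ex = np.exp(-kappa * r)
        e += qq * lb * (ex / r - shift)
        g = qq * lb * ex * (kappa * r + 1.0) / (r2 * r)  # -dU/dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def morse_forces(pos, pi, pj, depth, a, r0, f):
    e = 0.0
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        ex = np.exp(-a * (r - r0))
        om = 1.0 - ex
        e += depth[m] * (om * om - 1.0)
        dudr = 2.0 * depth[m] * a * ex * om
        g = -dudr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def gauss_forces(pos, pi, pj, eps, r0, sigma, f):
    e = 0.0
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - r0[m]
        s2 = sigma[m] * sigma[m]
        ex = np.exp(-dr * dr / (2.0 * s2))
        e += -eps[m] * ex
        dudr = eps[m] * dr / s2 * ex
        g = -dudr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def hb_well_forces(pos, loops, depth, sigma, r0, elig, tgt_z, w_ax, f, chosen):
    """Sliding hydrogen-bond wells: each loop bead binds the nearest
    eligible phosphate within the axial binding window around the loop's
    structural target (orientational specificity stand-in)."""
    e = 0.0
    for w in range(loops.shape[0]):
        i = loops[w]
        best = 1e30
        jb = -1
        for m in range(elig.shape[0]):
            j = elig[m]
            dzw = pos[j, 2] - tgt_z[w]
            if dzw > w_ax or dzw < -w_ax:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
                jb = j
        chosen[w] = jb
        if jb < 0:
            continue
        dx = pos[i, 0] - pos[jb, 0]
        dy = pos[i, 1] - pos[jb, 1]
        dz = pos[i, 2] - pos[jb, 2]
        r = np.sqrt(best)
        dr = r - r0
        s2 = sigma * sigma
        ex = np.exp(-dr * dr / (2.0 * s2))
        e += -depth[w] * ex
        if r > 1e-12:
            dudr = depth[w] * dr / s2 * ex
            g = -dudr / r
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[jb, 0] -= g * dx
            f[jb, 1] -= g * dy
            f[jb, 2] -= g * dz
    return e


@njit(**NB_OPTS)
def total_forces(
    pos, f,
    bonds, bond_k, bond_r0,
    angles, angle_k, angle_t0,
    rest_idx, rest_k, rest_pos,
    loop_idx, loop_k, loop_target,
    ev_i, ev_j, n_ev, radius, eps_ev, partner,
    el_i, el_j, n_el, q_intra, q_cross, is_dna, lb, kappa, rcut,
    pair_i, pair_j, pair_depth, morse_a, r0_bp,
    gw_i, gw_j, gw_eps, gw_r0, gw_sig,
    well_loop, well_depth, sig_hb, r0_hb, elig, well_tgt_z, w_ax, chosen,
):
    for i in range(f.shape[0]):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = bond_forces(pos, bonds, bond_k, bond_r0, f)
    e += angle_forces(pos, angles, angle_k, angle_t0, f)
    e += restraint_forces(pos, rest_idx, rest_k, rest_pos, f)
    e += restraint_forces(pos, loop_idx, loop_k, loop_target, f)
    e += ev_forces(pos, radius, ev_i, ev_j, n_ev, eps_ev, partner, f)
    e += elec_forces(pos, q_intra, q_cross, is_dna, el_i, el_j, n_el, lb,
                     kappa, rcut, f)
    e += morse_forces(pos, pair_i, pair_j, pair_depth, morse_a, r0_bp, f)
    e += gauss_forces(pos, gw_i, gw_j, gw_eps, gw_r0, gw_sig, f)
    e += hb_well_forces(pos, well_loop, well_depth, sig_hb, r0_hb, elig,
                        well_tgt_z, w_ax, f, chosen)
    return e


@njit(**NB_OPTS)
def baoab_chunk(
    pos, vel, f, mobile, inv_mass, noise, dt, gamma, temperature,
    bonds, bond_k, bond_r0,
    angles, angle_k, angle_t0,
    rest_idx, rest_k, rest_pos,
    loop_idx, loop_k, loop_target,
    ev_i, ev_j, n_ev, radius, eps_ev, partner,
    el_i, el_j, n_el, q_intra, q_cross, is_dna, lb, kappa, rcut,
    pair_i, pair_j, pair_depth, morse_a, r0_bp,
    gw_i, gw_j, gw_eps, gw_r0, gw_sig,
    well_loop, well_depth, sig_hb, r0_hb, elig, well_tgt_z, w_ax, chosen,
):
    """Run ``noise.shape[0]`` BAOAB steps; returns the last total energy.

    ``noise`` has shape (nsteps, n_mobile, 3); rows map to mobile beads in
    index order.  The pair lists are assumed valid for the whole chunk.
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt)
    tfac = temperature * (1.0 - c1 * c1)
    half = 0.5 * dt
    e = 0.0
    for s in range(nsteps):
        # B: half kick
        for i in range(n):
            if mobile[i] == 1:
                vel[i, 0] += half * f[i, 0] * inv_mass[i]
                vel[i, 1] += half * f[i, 1] * inv_mass[i]
                vel[i, 2] += half * f[i, 2] * inv_mass[i]
        # A: half drift
        for i in range(n):
            if mobile[i] == 1:
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
        # O: Ornstein-Uhlenbeck
        m = 0
        for i in range(n):
            if mobile[i] == 1:
                c3 = np.sqrt(tfac * inv_mass[i])
                vel[i, 0] = c1 * vel[i, 0] + c3 * noise[s, m, 0]
                vel[i, 1] = c1 * vel[i, 1] + c3 * noise[s, m, 1]
                vel[i, 2] = c1 * vel[i, 2] + c3 * noise[s, m, 2]
                m += 1
        # A: half drift
        for i in range(n):
            if mobile[i] == 1:
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
        # force refresh + B: half kick
        e = total_forces(
            pos, f,
            bonds, bond_k, bond_r0,
            angles, angle_k, angle_t0,
            rest_idx, rest_k, rest_pos,
            loop_idx, loop_k, loop_target,
            ev_i, ev_j, n_ev, radius, eps_ev, partner,
            el_i, el_j, n_el, q_intra, q_cross, is_dna, lb, kappa, rcut,
            pair_i, pair_j, pair_depth, morse_a, r0_bp,
            gw_i, gw_j, gw_eps, gw_r0, gw_sig,
            well_loop, well_depth, sig_hb, r0_hb, elig, well_tgt_z, w_ax,
            chosen,
        )
        for i in range(n):
            if mobile[i] == 1:
                vel[i, 0] += half * f[i, 0] * inv_mass[i]
                vel[i, 1] += half * f[i, 1] * inv_mass[i]
                vel[i, 2] += half * f[i, 2] * inv_mass[i]
    return e
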