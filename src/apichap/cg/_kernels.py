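"""Numba force/energy and Langevin-integration kernels.

Everything here operates on flat arrays prepared by CGSystem; the public
API lives in integrate.py.  Energy-term order in the returned vector:
[bond, angle, dihedral, native, repulsion, debye_huckel, hydrophobic].
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_TERMS = 7
OVERLAP_R = 0.1      # Å; closer than this is treated as a fault
MAX_STEP_DISP = 10.0  # Å per step; larger means the integrator blew up


@njit(cache=True, inline="always")
def _min_image(d, box, pbc):
    if pbc:
        for a in range(3):
            d[a] -= box * np.round(d[a] / box)
    return d


@njit(cache=True)
def forces_energies(pos, box, pbc,
                    bonds, bond_r0, k_bond,
                    angles, angle_th0, k_angle,
                    dihedrals, dihedral_phi0, k_dih,
                    native_pairs, native_r0, native_qq, eps_native,
                    nb_pairs, nb_qq, nb_hh,
                    eps_rep, sigma_rep,
                    dh_b, dh_lam, lambda_hp, sigma_hp):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energies = np.zeros(N_TERMS)
    bad_i = -1
    bad_j = -1
    d = np.empty(3)

    # bonds
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        for a in range(3):
            d[a] = pos[i, a] - pos[j, a]
        _min_image(d, box, pbc)
        r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - bond_r0[b]
        energies[0] += 0.5 * k_bond * dr * dr
        fmag = -k_bond * dr / r
        for a in range(3):
            forces[i, a] += fmag * d[a]
            forces[j, a] -= fmag * d[a]

    # angles (harmonic in theta)
    v1 = np.empty(3)
    v2 = np.empty(3)
    for t in range(angles.shape[0]):
        i, j, k = angles[t, 0], angles[t, 1], angles[t, 2]
        for a in range(3):
            v1[a] = pos[i, a] - pos[j, a]
            v2[a] = pos[k, a] - pos[j, a]
        _min_image(v1, box, pbc)
        _min_image(v2, box, pbc)
        r1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
        r2 = np.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
        cost = (v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]) / (r1 * r2)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        dth = theta - angle_th0[t]
        energies[1] += 0.5 * k_angle * dth * dth
        # F_i = -dU/dtheta * dtheta/dr_i = (dU/dtheta / sin) * dcos/dr_i
        du = k_angle * dth
        coef = du / sint
        for a in range(3):
            gi = (v2[a] / (r1 * r2) - cost * v1[a] / (r1 * r1))
            gk = (v1[a] / (r1 * r2) - cost * v2[a] / (r2 * r2))
            fi = coef * gi
            fk = coef * gk
            forces[i, a] += fi
            forces[k, a] += fk
            forces[j, a] -= fi + fk
    # dihedrals: U = kd*[(1-cos(dphi)) + 0.5*(1-cos(3*dphi))]
    b1 = np.empty(3)
    b2 = np.empty(3)
    b3 = np.empty(3)
    m = np.empty(3)
    nn = np.empty(3)
    for t in range(dihedrals.shape[0]):
        i, j, k, l = (dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2],
                      dihedrals[t, 3])
        for a in range(3):
            b1[a] = pos[j, a] - pos[i, a]
            b2[a] = pos[k, a] - pos[j, a]
            b3[a] = pos[l, a] - pos[k, a]
        _min_image(b1, box, pbc)
        _min_image(b2, box, pbc)
        _min_image(b3, box, pbc)
        m[0] = b1[1] * b2[2] - b1[2] * b2[1]
        m[1] = b1[2] * b2[0] - b1[0] * b2[2]
        m[2] = b1[0] * b2[1] - b1[1] * b2[0]
        nn[0] = b2[1] * b3[2] - b2[2] * b3[1]
        nn[1] = b2[2] * b3[0] - b2[0] * b3[2]
        nn[2] = b2[0] * b3[1] - b2[1] * b3[0]
        mm = m[0] ** 2 + m[1] ** 2 + m[2] ** 2
        nn2 = nn[0] ** 2 + nn[1] ** 2 + nn[2] ** 2
        nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        if mm < 1e-12 or nn2 < 1e-12:
            continue
        x = m[0] * nn[0] + m[1] * nn[1] + m[2] * nn[2]
        cx0 = m[1] * nn[2] - m[2] * nn[1]
        cx1 = m[2] * nn[0] - m[0] * nn[2]
        cx2 = m[0] * nn[1] - m[1] * nn[0]
        y = (cx0 * b2[0] + cx1 * b2[1] + cx2 * b2[2]) / nb2
        phi = np.arctan2(y, x)
        dphi = phi - dihedral_phi0[t]
        energies[2] += k_dih * ((1.0 - np.cos(dphi))
                                + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        du = k_dih * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))  # dU/dphi
        # dphi/dr_i = -(|b2|/|m|^2) m ; dphi/dr_l = (|b2|/|n|^2) n
        pref_i = du * nb2 / mm
        pref_l = -du * nb2 / nn2
        tdot = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
        sdot = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
        for a in range(3):
            fi = pref_i * m[a]
            fl = pref_l * nn[a]
            fj = -(1.0 + tdot) * fi + sdot * fl
            fk = tdot * fi - (1.0 + sdot) * fl
            forces[i, a] += fi
            forces[j, a] += fj
            forces[k, a] += fk
            forces[l, a] += fl

    # native 12-10 Lennard-Jones (+ electrostatics on charged native pairs)
    for p in range(native_pairs.shape[0]):
        i, j = native_pairs[p, 0], native_pairs[p, 1]
        for a in range(3):
            d[a] = pos[i, a] - pos[j, a]
        _min_image(d, box, pbc)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        r = np.sqrt(r2)
        if r < OVERLAP_R:
            bad_i, bad_j = i, j
        s = native_r0[p] / r
        s10 = s ** 10
        s12 = s10 * s * s
        energies[3] += eps_native * (5.0 * s12 - 6.0 * s10)
        fmag = 60.0 * eps_native * (s12 - s10) / r2  # -dU/dr / r
        qq = native_qq[p]
        if qq != 0.0 and dh_b != 0.0:
            u = dh_b * qq * np.exp(-r / dh_lam) / r
            energies[5] += u
            fmag += u * (1.0 / dh_lam + 1.0 / r) / r
        for a in range(3):
            forces[i, a] += fmag * d[a]
            forces[j, a] -= fmag * d[a]

    # nonbonded: repulsion + Debye-Hueckel + truncated hydrophobic well
    hp_cut = 2.0 * sigma_hp
    # shift so the hydrophobic well is continuous at its cutoff
    sc6 = 0.015625  # (1/2)^6
    u_shift = sc6 * sc6 - 2.0 * sc6
    for p in range(nb_pairs.shape[0]):
        i, j = nb_pairs[p, 0], nb_pairs[p, 1]
        for a in range(3):
            d[a] = pos[i, a] - pos[j, a]
        _min_image(d, box, pbc)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        r = np.sqrt(r2)
        if r < OVERLAP_R:
            bad_i, bad_j = i, j
            r = OVERLAP_R
            r2 = r * r
        sr = sigma_rep / r
        sr12 = sr ** 12
        energies[4] += eps_rep * sr12
        fmag = 12.0 * eps_rep * sr12 / r2
        qq = nb_qq[p]
        if qq != 0.0 and dh_b != 0.0:
            u = dh_b * qq * np.exp(-r / dh_lam) / r
            energies[5] += u
            fmag += u * (1.0 / dh_lam + 1.0 / r) / r
        hh = nb_hh[p]
        if hh != 0.0 and lambda_hp != 0.0 and r < hp_cut:
            sh6 = (sigma_hp / r) ** 6
            sh12 = sh6 * sh6
            energies[6] += lambda_hp * hh * (sh12 - 2.0 * sh6 - u_shift)
            # -dU/dr / r with dU/dr = lambda*hh*(-12 s12 + 12 s6)/r
            fmag += 12.0 * lambda_hp * hh * (sh12 - sh6) / r2
        for a in range(3):
            forces[i, a] += fmag * d[a]
            forces[j, a] -= fmag * d[a]

    return forces, energies, bad_i, bad_j


@njit(cache=True)
def run_block(pos, vel, forces, noise, dt, c1, c2,
              box, pbc,
              bonds, bond_r0, k_bond,
              angles, angle_th0, k_angle,
              dihedrals, dihedral_phi0, k_dih,
              native_pairs, native_r0, native_qq, eps_native,
              nb_pairs, nb_qq, nb_hh,
              eps_rep, sigma_rep,
              dh_b, dh_lam, lambda_hp, sigma_hp):
    """BAOAB steps, one per noise row, updating pos/vel/forces in place.

    Returns (status, bad_i, bad_j): status 0 ok, 1 bead overlap,
    2 per-step displacement exceeded MAX_STEP_DISP.
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    half = 0.5 * dt
    for s in range(n_steps):
        max_d2 = 0.0
        for i in range(n):
            for a in range(3):
                vel[i, a] += half * forces[i, a]
                old = pos[i, a]
                pos[i, a] += half * vel[i, a]
                vel[i, a] = c1 * vel[i, a] + c2 * noise[s, i, a]
                pos[i, a] += half * vel[i, a]
                dd = pos[i, a] - old
                max_d2 = max(max_d2, dd * dd)
        if max_d2 > MAX_STEP_DISP * MAX_STEP_DISP:
            return 2, -1, -1
        f, _, bi, bj = forces_energies(
            pos, box, pbc, bonds, bond_r0, k_bond,
            angles, angle_th0, k_angle,
            dihedrals, dihedral_phi0, k_dih,
            native_pairs, native_r0, native_qq, eps_native,
            nb_pairs, nb_qq, nb_hh, eps_rep, sigma_rep,
            dh_b, dh_lam, lambda_hp, sigma_hp)
        if bi >= 0:
            return 1, bi, bj
        for i in range(n):
            for a in range(3):
                forces[i, a] = f[i, a]
                vel[i, a] += half * f[i, a]
    return 0, -1, -1
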