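"""Numba kernels for the hot inner loops (bead forces, contact CVs, dihedrals).

These mirror the vectorised numpy implementations exactly; the numpy versions
remain the readable reference and the test suite pins the two against each
other and against finite differences.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def bead_energy_forces(c, bonds, bond_r0, bond_k, angles, cos0, angle_k,
                       dihedrals, dihedral_k, nb_pairs, nb_sigma, nb_attr,
                       k_rep, eps_attr, attr_width, cutoff):
    n = c.shape[0]
    f = np.zeros((n, 3))
    e = 0.0
    # bonds
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = c[i, 0] - c[j, 0]
        dy = c[i, 1] - c[j, 1]
        dz = c[i, 2] - c[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e += bond_k[b] * dr * dr
        coef = -2.0 * bond_k[b] * dr / r
        f[i, 0] += coef * dx; f[i, 1] += coef * dy; f[i, 2] += coef * dz
        f[j, 0] -= coef * dx; f[j, 1] -= coef * dy; f[j, 2] -= coef * dz
    # angles: U = k (cos th - cos th0)^2
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux, uy, uz = c[i, 0] - c[j, 0], c[i, 1] - c[j, 1], c[i, 2] - c[j, 2]
        vx, vy, vz = c[k, 0] - c[j, 0], c[k, 1] - c[j, 1], c[k, 2] - c[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        eux, euy, euz = ux / nu, uy / nu, uz / nu
        evx, evy, evz = vx / nv, vy / nv, vz / nv
        cth = eux * evx + euy * evy + euz * evz
        d = cth - cos0
        e += angle_k * d * d
        coef = -2.0 * angle_k * d
        gix = (evx - cth * eux) / nu
        giy = (evy - cth * euy) / nu
        giz = (evz - cth * euz) / nu
        gkx = (eux - cth * evx) / nv
        gky = (euy - cth * evy) / nv
        gkz = (euz - cth * evz) / nv
        f[i, 0] += coef * gix; f[i, 1] += coef * giy; f[i, 2] += coef * giz
        f[k, 0] += coef * gkx; f[k, 1] += coef * gky; f[k, 2] += coef * gkz
        f[j, 0] -= coef * (gix + gkx); f[j, 1] -= coef * (giy + gky); f[j, 2] -= coef * (giz + gkz)
    # dihedrals: U = k (1 + cos phi), gradient regularised at collinear
    for dd in range(dihedrals.shape[0]):
        i1, i2, i3, i4 = dihedrals[dd, 0], dihedrals[dd, 1], dihedrals[dd, 2], dihedrals[dd, 3]
        b1x, b1y, b1z = c[i2, 0] - c[i1, 0], c[i2, 1] - c[i1, 1], c[i2, 2] - c[i1, 2]
        b2x, b2y, b2z = c[i3, 0] - c[i2, 0], c[i3, 1] - c[i2, 1], c[i3, 2] - c[i2, 2]
        b3x, b3y, b3z = c[i4, 0] - c[i3, 0], c[i4, 1] - c[i3, 1], c[i4, 2] - c[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 1e-12)
        n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 1e-12)
        nb2 = max(np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z), 1e-12)
        x = n1x * n2x + n1y * n2y + n1z * n2z
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phi = np.arctan2(y, x)
        e += dihedral_k * (1.0 + np.cos(phi))
        coef = dihedral_k * np.sin(phi)
        s1 = -nb2 / n1sq
        s4 = nb2 / n2sq
        f1x, f1y, f1z = s1 * n1x, s1 * n1y, s1 * n1z
        f4x, f4y, f4z = s4 * n2x, s4 * n2y, s4 * n2z
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        f[i1, 0] += coef * f1x; f[i1, 1] += coef * f1y; f[i1, 2] += coef * f1z
        f[i2, 0] += coef * (-(1.0 + p) * f1x + q * f4x)
        f[i2, 1] += coef * (-(1.0 + p) * f1y + q * f4y)
        f[i2, 2] += coef * (-(1.0 + p) * f1z + q * f4z)
        f[i3, 0] += coef * (p * f1x - (1.0 + q) * f4x)
        f[i3, 1] += coef * (p * f1y - (1.0 + q) * f4y)
        f[i3, 2] += coef * (p * f1z - (1.0 + q) * f4z)
        f[i4, 0] += coef * f4x; f[i4, 1] += coef * f4y; f[i4, 2] += coef * f4z
    # nonbonded: soft-sphere repulsion + Gaussian contact attraction
    for pp in range(nb_pairs.shape[0]):
        i, j = nb_pairs[pp, 0], nb_pairs[pp, 1]
        dx = c[i, 0] - c[j, 0]
        dy = c[i, 1] - c[j, 1]
        dz = c[i, 2] - c[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= cutoff:
            continue
        if r < 1e-8:
            r = 1e-8
        sig = nb_sigma[pp]
        dudr = 0.0
        if r < sig:
            t = 1.0 - r / sig
            e += k_rep * t * t
            dudr -= 2.0 * k_rep * t / sig
        if nb_attr[pp]:
            dr = r - sig
            g = np.exp(-dr * dr / (2.0 * attr_width * attr_width))
            e += -eps_attr * g
            dudr += eps_attr * g * dr / (attr_width * attr_width)
        coef = -dudr / r
        f[i, 0] += coef * dx; f[i, 1] += coef * dy; f[i, 2] += coef * dz
        f[j, 0] -= coef * dx; f[j, 1] -= coef * dy; f[j, 2] -= coef * dz
    return e, f


@numba.njit(cache=True)
def contact_sum(c, idx_i, idx_j, r0, n, m):
    """Rational-switching contact count and gradient over fixed pairs."""
    nat = c.shape[0]
    grad = np.zeros((nat, 3))
    total = 0.0
    for p in range(idx_i.shape[0]):
        i, j = idx_i[p], idx_j[p]
        dx = c[i, 0] - c[j, 0]
        dy = c[i, 1] - c[j, 1]
        dz = c[i, 2] - c[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-10:
            return np.nan, grad
        x = r / r0
        if abs(x - 1.0) < 1e-6:
            s = n / m + (n * (n - m) / (2.0 * m)) * (x - 1.0)
            dsdx = n * (n - m) / (2.0 * m)
        else:
            xn = x**n
            xm = x**m
            den = 1.0 - xm
            s = (1.0 - xn) / den
            dsdx = (-n * x ** (n - 1) * den + m * x ** (m - 1) * (1.0 - xn)) / (den * den)
        total += s
        coef = dsdx / r0 / r
        grad[i, 0] += coef * dx; grad[i, 1] += coef * dy; grad[i, 2] += coef * dz
        grad[j, 0] -= coef * dx; grad[j, 1] -= coef * dy; grad[j, 2] -= coef * dz
    return total, grad


@numba.njit(cache=True)
def dihedral_phis_grads(c, quads):
    """Dihedral values and gradients over index quadruples; flag=False if degenerate."""
    nq = quads.shape[0]
    phis = np.zeros(nq)
    grads = np.zeros((nq, 4, 3))
    ok = True
    for dd in range(nq):
        i1, i2, i3, i4 = quads[dd, 0], quads[dd, 1], quads[dd, 2], quads[dd, 3]
        b1x, b1y, b1z = c[i2, 0] - c[i1, 0], c[i2, 1] - c[i1, 1], c[i2, 2] - c[i1, 2]
        b2x, b2y, b2z = c[i3, 0] - c[i2, 0], c[i3, 1] - c[i2, 1], c[i3, 2] - c[i2, 2]
        b3x, b3y, b3z = c[i4, 0] - c[i3, 0], c[i4, 1] - c[i3, 1], c[i4, 2] - c[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-18 or n2sq < 1e-18 or nb2 < 1e-12:
            ok = False
            continue
        x = n1x * n2x + n1y * n2y + n1z * n2z
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phis[dd] = np.arctan2(y, x)
        s1 = -nb2 / n1sq
        s4 = nb2 / n2sq
        p = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        q = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        grads[dd, 0, 0] = s1 * n1x
        grads[dd, 0, 1] = s1 * n1y
        grads[dd, 0, 2] = s1 * n1z
        grads[dd, 3, 0] = s4 * n2x
        grads[dd, 3, 1] = s4 * n2y
        grads[dd, 3, 2] = s4 * n2z
        for k in range(3):
            grads[dd, 1, k] = -(1.0 + p) * grads[dd, 0, k] + q * grads[dd, 3, k]
            grads[dd, 2, k] = p * grads[dd, 0, k] - (1.0 + q) * grads[dd, 3, k]
    return phis, grads, ok
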