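"""Numba-compiled element kernels for the wall solver.

Fused loops over elements and Gauss points for the Neo-Hookean residual,
consistent tangent, and follower-pressure face terms.  These are pure
low-level computations; all bookkeeping stays in :mod:`aaafsi.wall_fem`.
Compiled artifacts are cached on disk, so the JIT cost is paid once.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def residual_and_stress(u, elems, dNdX, detJ0, w27, mu, lam, sigma0, use_sigma0):
    """Internal nodal forces and gauss Cauchy stress.

    Returns (fint (n,3), sig (ne,27,3,3), ok); ok is False on element
    inversion (det F <= 0), in which case the other outputs are invalid.
    """
    ne = elems.shape[0]
    nn = u.shape[0]
    fint = np.zeros((nn, 3))
    sig = np.empty((ne, 27, 3, 3))
    F = np.empty((3, 3))
    Fi = np.empty((3, 3))
    B = np.empty((3, 3))
    dNdx = np.empty((27, 3))
    for e in range(ne):
        for g in range(27):
            for i in range(3):
                for j in range(3):
                    F[i, j] = 1.0 if i == j else 0.0
            for n in range(27):
                node = elems[e, n]
                for i in range(3):
                    ui = u[node, i]
                    for j in range(3):
                        F[i, j] += ui * dNdX[e, g, n, j]
            J = (
                F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
            )
            if J <= 0.0:
                return fint, sig, False
            inv_det = 1.0 / J
            Fi[0, 0] = (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]) * inv_det
            Fi[0, 1] = (F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]) * inv_det
            Fi[0, 2] = (F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]) * inv_det
            Fi[1, 0] = (F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]) * inv_det
            Fi[1, 1] = (F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]) * inv_det
            Fi[1, 2] = (F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]) * inv_det
            Fi[2, 0] = (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]) * inv_det
            Fi[2, 1] = (F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]) * inv_det
            Fi[2, 2] = (F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]) * inv_det
            for n in range(27):
                for j in range(3):
                    dNdx[n, j] = (
                        dNdX[e, g, n, 0] * Fi[0, j]
                        + dNdX[e, g, n, 1] * Fi[1, j]
                        + dNdX[e, g, n, 2] * Fi[2, j]
                    )
            for i in range(3):
                for j in range(3):
                    B[i, j] = F[i, 0] * F[j, 0] + F[i, 1] * F[j, 1] + F[i, 2] * F[j, 2]
            coef_dev = mu / J
            coef_vol = lam * np.log(J) / J
            for i in range(3):
                for j in range(3):
                    s = coef_dev * (B[i, j] - (1.0 if i == j else 0.0))
                    if i == j:
                        s += coef_vol
                    if use_sigma0:
                        s += sigma0[e, g, i, j]
                    sig[e, g, i, j] = s
            wgt = w27[g] * detJ0[e, g] * J
            for n in range(27):
                node = elems[e, n]
                for i in range(3):
                    acc = 0.0
                    for j in range(3):
                        acc += sig[e, g, i, j] * dNdx[n, j]
                    fint[node, i] += wgt * acc
    return fint, sig, True


@njit(cache=True, fastmath=True)
def tangent_blocks(u, elems, dNdX, detJ0, w27, mu, lam, sigma0, use_sigma0):
    """Element tangent matrices (ne, 81, 81): material + geometric parts.

    Dof ordering within an element is (node, component).
    Returns (K_el, ok); ok False on inversion.
    """
    ne = elems.shape[0]
    K = np.zeros((ne, 81, 81))
    F = np.empty((3, 3))
    Fi = np.empty((3, 3))
    B = np.empty((3, 3))
    s = np.empty((3, 3))
    dNdx = np.empty((27, 3))
    sg = np.empty((27, 3))  # sigma . dNdx per node
    for e in range(ne):
        for g in range(27):
            for i in range(3):
                for j in range(3):
                    F[i, j] = 1.0 if i == j else 0.0
            for n in range(27):
                node = elems[e, n]
                for i in range(3):
                    ui = u[node, i]
                    for j in range(3):
                        F[i, j] += ui * dNdX[e, g, n, j]
            J = (
                F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
                - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
                + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
            )
            if J <= 0.0:
                return K, False
            inv_det = 1.0 / J
            Fi[0, 0] = (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]) * inv_det
            Fi[0, 1] = (F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]) * inv_det
            Fi[0, 2] = (F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]) * inv_det
            Fi[1, 0] = (F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]) * inv_det
            Fi[1, 1] = (F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]) * inv_det
            Fi[1, 2] = (F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]) * inv_det
            Fi[2, 0] = (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]) * inv_det
            Fi[2, 1] = (F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]) * inv_det
            Fi[2, 2] = (F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]) * inv_det
            for n in range(27):
                for j in range(3):
                    dNdx[n, j] = (
                        dNdX[e, g, n, 0] * Fi[0, j]
                        + dNdX[e, g, n, 1] * Fi[1, j]
                        + dNdX[e, g, n, 2] * Fi[2, j]
                    )
            for i in range(3):
                for j in range(3):
                    B[i, j] = F[i, 0] * F[j, 0] + F[i, 1] * F[j, 1] + F[i, 2] * F[j, 2]
            lnJ = np.log(J)
            coef_dev = mu / J
            coef_vol = lam * lnJ / J
            for i in range(3):
                for j in range(3):
                    s[i, j] = coef_dev * (B[i, j] - (1.0 if i == j else 0.0))
                    if i == j:
                        s[i, j] += coef_vol
                    if use_sigma0:
                        s[i, j] += sigma0[e, g, i, j]
            wgt = w27[g] * detJ0[e, g] * J
            lamp = wgt * lam / J
            mup = wgt * (mu - lam * lnJ) / J
            for n in range(27):
                for i in range(3):
                    sg[n, i] = (
                        s[i, 0] * dNdx[n, 0] + s[i, 1] * dNdx[n, 1] + s[i, 2] * dNdx[n, 2]
                    )
            for a in range(27):
                da0, da1, da2 = dNdx[a, 0], dNdx[a, 1], dNdx[a, 2]
                for b in range(27):
                    db0, db1, db2 = dNdx[b, 0], dNdx[b, 1], dNdx[b, 2]
                    dot = da0 * db0 + da1 * db1 + da2 * db2
                    # geometric term: dNa_j sigma_jl dNb_l (on the diagonal)
                    geo = wgt * (sg[a, 0] * db0 + sg[a, 1] * db1 + sg[a, 2] * db2)
                    diag = mup * dot + geo
                    for i in range(3):
                        dai = dNdx[a, i]
                        for k in range(3):
                            v = lamp * dai * dNdx[b, k] + mup * dNdx[a, k] * dNdx[b, i]
                            if i == k:
                                v += diag
                            K[e, 3 * a + i, 3 * b + k] += v
    return K, True


@njit(cache=True, fastmath=True)
def face_forces(x, faces, p_nodal, face_n, face_dn, face_w, sign):
    """Follower-pressure nodal forces on the luminal faces."""
    nf = faces.shape[0]
    nn = x.shape[0]
    fext = np.zeros((nn, 3))
    xxi = np.empty(3)
    xeta = np.empty(3)
    for f in range(nf):
        for g in range(9):
            for i in range(3):
                xxi[i] = 0.0
                xeta[i] = 0.0
            pg = 0.0
            for n in range(9):
                node = faces[f, n]
                pg += face_n[g, n] * p_nodal[node]
                for i in range(3):
                    xxi[i] += face_dn[g, n, 0] * x[node, i]
                    xeta[i] += face_dn[g, n, 1] * x[node, i]
            n0 = xxi[1] * xeta[2] - xxi[2] * xeta[1]
            n1 = xxi[2] * xeta[0] - xxi[0] * xeta[2]
            n2 = xxi[0] * xeta[1] - xxi[1] * xeta[0]
            coef = sign * face_w[g] * pg
            for n in range(9):
                node = faces[f, n]
                fn = face_n[g, n]
                fext[node, 0] += coef * fn * n0
                fext[node, 1] += coef * fn * n1
                fext[node, 2] += coef * fn * n2
    return fext


@njit(cache=True, fastmath=True)
def face_stiffness(x, faces, p_nodal, face_n, face_dn, face_w, sign):
    """Load stiffness d f_ext / d x of the follower pressure, (nf, 27, 27)."""
    nf = faces.shape[0]
    K = np.zeros((nf, 27, 27))
    xxi = np.empty(3)
    xeta = np.empty(3)
    for f in range(nf):
        for g in range(9):
            for i in range(3):
                xxi[i] = 0.0
                xeta[i] = 0.0
            pg = 0.0
            for n in range(9):
                node = faces[f, n]
                pg += face_n[g, n] * p_nodal[node]
                for i in range(3):
                    xxi[i] += face_dn[g, n, 0] * x[node, i]
                    xeta[i] += face_dn[g, n, 1] * x[node, i]
            coef = sign * face_w[g] * pg
            for a in range(9):
                ca = coef * face_n[g, a]
                for b in range(9):
                    d0 = face_dn[g, b, 0]
                    d1 = face_dn[g, b, 1]
                    # dn_i/dx_bk = d0 eps_ikm xeta_m + d1 eps_ilk xxi_l
                    K[f, 3 * a + 0, 3 * b + 1] += ca * (d0 * xeta[2] - d1 * xxi[2])
                    K[f, 3 * a + 0, 3 * b + 2] += ca * (-d0 * xeta[1] + d1 * xxi[1])
                    K[f, 3 * a + 1, 3 * b + 0] += ca * (-d0 * xeta[2] + d1 * xxi[2])
                    K[f, 3 * a + 1, 3 * b + 2] += ca * (d0 * xeta[0] - d1 * xxi[0])
                    K[f, 3 * a + 2, 3 * b + 0] += ca * (d0 * xeta[1] - d1 * xxi[1])
                    K[f, 3 * a + 2, 3 * b + 1] += ca * (-d0 * xeta[0] + d1 * xxi[0])
    return K
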