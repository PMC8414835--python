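"""Triquadratic (27-node) hexahedral element tables.

Shape functions are tensor products of 1D quadratic Lagrange polynomials on
[-1, 1] with nodes at xi = -1, 0, +1.  Local node ``n`` maps to the lattice
triple ``(a, b, c)`` with ``n = a + 3*b + 9*c`` (lexicographic).  The same
convention is used for the 9-node quadratic faces (``n = a + 3*b``).

All tables are evaluated once at 3x3x3 (volume) and 3x3 (face) Gauss points
and cached at module import; solvers index into them directly.
"""

from __future__ import annotations

import numpy as np

# 1D 3-point Gauss rule
_GP_1D = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_GW_1D = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def _lagrange_quadratic(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of the three 1D quadratic Lagrange basis
    functions at points ``xi``; shapes (len(xi), 3)."""
    xi = np.asarray(xi, dtype=float)
    n = np.stack([0.5 * xi * (xi - 1.0), 1.0 - xi**2, 0.5 * xi * (xi + 1.0)], axis=-1)
    d = np.stack([xi - 0.5, -2.0 * xi, xi + 0.5], axis=-1)
    return n, d


def hex27_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (N, dN, w) at the 27 Gauss points of a 27-node hexahedron.

    N   : (27 gp, 27 nodes)
    dN  : (27 gp, 27 nodes, 3) derivatives w.r.t. (xi, eta, zeta)
    w   : (27 gp,) quadrature weights
    """
    pts = np.array([(x, y, z) for z in _GP_1D for y in _GP_1D for x in _GP_1D])
    wts = np.array([wz * wy * wx for wz in _GW_1D for wy in _GW_1D for wx in _GW_1D])
    nx, dx = _lagrange_quadratic(pts[:, 0])
    ny, dy = _lagrange_quadratic(pts[:, 1])
    nz, dz = _lagrange_quadratic(pts[:, 2])
    ngp = pts.shape[0]
    N = np.empty((ngp, 27))
    dN = np.empty((ngp, 27, 3))
    for c in range(3):
        for b in range(3):
            for a in range(3):
                n = a + 3 * b + 9 * c
                N[:, n] = nx[:, a] * ny[:, b] * nz[:, c]
                dN[:, n, 0] = dx[:, a] * ny[:, b] * nz[:, c]
                dN[:, n, 1] = nx[:, a] * dy[:, b] * nz[:, c]
                dN[:, n, 2] = nx[:, a] * ny[:, b] * dz[:, c]
    return N, dN, wts


def quad9_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (N, dN, w) at the 9 Gauss points of a 9-node quadratic quad."""
    pts = np.array([(x, y) for y in _GP_1D for x in _GP_1D])
    wts = np.array([wy * wx for wy in _GW_1D for wx in _GW_1D])
    nx, dx = _lagrange_quadratic(pts[:, 0])
    ny, dy = _lagrange_quadratic(pts[:, 1])
    ngp = pts.shape[0]
    N = np.empty((ngp, 9))
    dN = np.empty((ngp, 9, 2))
    for b in range(3):
        for a in range(3):
            n = a + 3 * b
            N[:, n] = nx[:, a] * ny[:, b]
            dN[:, n, 0] = dx[:, a] * ny[:, b]
            dN[:, n, 1] = nx[:, a] * dy[:, b]
    return N, dN, wts


HEX_N, HEX_DN, HEX_W = hex27_tables()
FACE_N, FACE_DN, FACE_W = quad9_tables()


def jacobians(coords: np.ndarray) -> np.ndarray:
    """Determinant of the isoparametric map at every Gauss point.

    coords : (n_elem, 27, 3) nodal coordinates per element.
    returns (n_elem, 27 gp) determinants.
    """
    # J[e, g, i, j] = d x_i / d xi_j
    J = np.einsum("gnk,enj->egjk", HEX_DN, coords)
    return np.linalg.det(J)
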