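"""Incompressible Neo-Hookean wall finite elements with pre-stress estimation.

The aneurysm wall is an isotropic Neo-Hookean solid, sigma = -p I + G (B - I),
with incompressibility enforced by a volumetric penalty (numerical Poisson
ratio 0.495, bulk-like modulus kappa = 2 G nu / (1 - 2 nu)).  Elements are
27-node triquadratic hexahedra with 3x3x3 Gauss quadrature; the luminal
pressure is a follower load (stays normal to the deforming surface); inlet and
outlet cross-sections may only move radially in their local cylindrical frames.

The wall stress present in the imaged, pressurized geometry is recovered with
the Backward Incremental Method: a sinusoidal pressure schedule is applied in
increments, each solved on the *measured* geometry with the previous
increment's Cauchy stress carried as initial stress, so the final stress field
equilibrates the measured pressure with (near-)zero displacement.

Internally SI units (m, Pa); mesh coordinates arrive in mm and pressures in
mmHg at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels as kern
from .elements import FACE_DN, FACE_N, FACE_W, HEX_DN, HEX_W
from .geometry import WallMesh

MMHG_TO_PA = 133.322

__all__ = [
    "Material",
    "WallState",
    "EndConstraint",
    "WallFem",
    "ConvergenceError",
    "neo_hookean_cauchy",
    "penalty_pressure",
    "assign_shear_modulus",
    "solve_static_inflation",
    "bim_prestress",
    "von_mises",
]

#: group shear moduli (MPa) keyed by maximum-diameter size class
GROUP_SHEAR_MODULI_MPA = {"S": 0.92, "M": 1.02, "L": 1.36}


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual_history=None, increment: int | None = None):
        super().__init__(msg)
        self.residual_history = residual_history or []
        self.increment = increment


@dataclass
class Material:
    """Nearly incompressible Neo-Hookean wall material."""

    G: float  # shear modulus, MPa
    #: numerical Poisson ratio (0.5 nominal).  0.495 keeps the volumetric
    #: strain under 1% at physiological pressures while keeping the penalty
    #: block of the tangent well-conditioned for the direct solver.
    nu: float = 0.495

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("shear modulus must be positive")
        if not (0.45 <= self.nu < 0.5):
            raise ValueError("numerical Poisson ratio must lie in [0.45, 0.5)")

    @property
    def E(self) -> float:
        """Young's modulus E = 2 G (1 + nu), MPa."""
        return 2.0 * self.G * (1.0 + self.nu)

    @property
    def lame_lambda_pa(self) -> float:
        """Penalty (first Lame) parameter in Pa."""
        return 2.0 * self.G * 1e6 * self.nu / (1.0 - 2.0 * self.nu)

    @property
    def G_pa(self) -> float:
        return self.G * 1e6


def assign_shear_modulus(group: str) -> Material:
    """Material for a size group: G = 0.92 / 1.02 / 1.36 MPa for S / M / L."""
    try:
        return Material(G=GROUP_SHEAR_MODULI_MPA[group])
    except KeyError:
        raise ValueError(f"unknown AAA size group {group!r}; expected S, M or L") from None


@dataclass
class WallState:
    """Equilibrium state of the wall relative to the measured geometry."""

    displacement: np.ndarray  # (n_nodes, 3) mm
    cauchy_stress: np.ndarray  # (n_elem, 27 gp, 3, 3) kPa
    applied_pressure: float  # mmHg (luminal, mean if a profile was applied)
    prestressed: bool = False

    def __post_init__(self) -> None:
        s = self.cauchy_stress
        if s.size and np.abs(s - np.swapaxes(s, -1, -2)).max() > 1e-9 * max(
            1.0, np.abs(s).max()
        ):
            raise ValueError("Cauchy stress must be symmetric")


@dataclass
class EndConstraint:
    """Radial-only constraint for one end cross-section."""

    node_ids: np.ndarray
    axis: np.ndarray  # unit longitudinal direction of the local cylinder frame
    origin: np.ndarray  # point on the axis, mm


# --------------------------------------------------------------------------- #
# pointwise constitutive law
# --------------------------------------------------------------------------- #


def neo_hookean_cauchy(F: np.ndarray, G: float, p: float | None = None, nu: float = 0.495) -> np.ndarray:
    """Cauchy stress sigma = -p I + G (B - I), B = F F^T.

    ``G`` in MPa gives stress in MPa.  If ``p`` is omitted the volumetric
    penalty p = -kappa ln(det F) / det F with kappa = 2 G nu / (1 - 2 nu) is
    used.  Raises on inverted states (det F <= 0).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError(f"inverted deformation state: det F = {J}")
    if p is None:
        p = penalty_pressure(F, G, nu)
    B = F @ F.T
    return -p * np.eye(3) + G * (B - np.eye(3))


def penalty_pressure(F: np.ndarray, G: float, nu: float = 0.495) -> float:
    """Penalty pressure term p = -kappa ln(J)/J, kappa = 2 G nu / (1 - 2 nu)."""
    J = float(np.linalg.det(np.asarray(F, dtype=float)))
    kappa = 2.0 * G * nu / (1.0 - 2.0 * nu)
    return -kappa * np.log(J) / J


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress sqrt(3/2 dev(s):dev(s)); broadcasts over
    leading axes of a (..., 3, 3) symmetric tensor field."""
    s = np.asarray(stress, dtype=float)
    tr = np.trace(s, axis1=-2, axis2=-1)[..., None, None] / 3.0
    dev = s - tr * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


# --------------------------------------------------------------------------- #
# finite-element machinery
# --------------------------------------------------------------------------- #

_EPS = np.zeros((3, 3, 3))
_EPS[0, 1, 2] = _EPS[1, 2, 0] = _EPS[2, 0, 1] = 1.0
_EPS[0, 2, 1] = _EPS[2, 1, 0] = _EPS[1, 0, 2] = -1.0
_I3 = np.eye(3)
_DUMMY_SIG = np.zeros((1, 1, 3, 3))


def _det3(a: np.ndarray) -> np.ndarray:
    """Determinant of a (..., 3, 3) stack (faster than np.linalg.det here)."""
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def _inv3(a: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Inverse of a (..., 3, 3) stack via the adjugate."""
    out = np.empty_like(a)
    out[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    out[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    out[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    out[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    out[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    out[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    out[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    out[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    out[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return out / det[..., None, None]


class WallFem:
    """Assembled Newton solver for one wall mesh + material.

    Precomputes reference-configuration quantities, the end-constraint
    reduction and the luminal face tables once; individual solves are then
    comparatively cheap, which matters inside the FSI loop.
    """

    def __init__(self, mesh: WallMesh, material: Material):
        self.mesh = mesh
        self.mat = material
        self.X = mesh.nodes * 1e-3  # m
        self.elems = mesh.hex_elements
        ne, nn = self.elems.shape[0], self.X.shape[0]
        self.n_nodes = nn

        # reference gradients
        Xe = self.X[self.elems]  # (ne, 27, 3)
        J0 = np.einsum("gnj,eni->egij", HEX_DN, Xe)  # dX_i/dxi_j
        self.detJ0 = np.linalg.det(J0)
        if self.detJ0.min() <= 0:
            raise ValueError("reference mesh has non-positive Jacobians")
        J0inv = np.linalg.inv(J0)
        self.dNdX = np.einsum("gnk,egkj->egnj", HEX_DN, J0inv)  # (ne, g, n, 3)

        # scatter map for assembly
        dof = (self.elems[:, :, None] * 3 + np.arange(3)).reshape(ne, 81)
        self.rows = np.repeat(dof, 81, axis=1).ravel()
        self.cols = np.tile(dof, (1, 81)).ravel()
        self.dofmap = dof

        # luminal pressure faces: zeta = -1 face of first-layer elements
        mel = mesh.nodes_per_ring // 2
        nel = (mesh.n_rings - 1) // 2
        self.faces = self.elems[: mel * nel, :9].copy()
        self._face_sign = self._orient_faces()
        self._fdof = (self.faces[:, :, None] * 3 + np.arange(3)).reshape(-1, 27)

        self.constraints = self._end_constraints()
        self.T = self._reduction_matrix()
        self._lu = None  # cached tangent factorization (modified Newton)
        self._paths: dict[str, list] = {}  # cached einsum contraction paths

    def _einsum(self, expr: str, *ops):
        path = self._paths.get(expr)
        if path is None:
            path = np.einsum_path(expr, *ops, optimize="optimal")[0]
            self._paths[expr] = path
        return np.einsum(expr, *ops, optimize=path)

    # -- constraints ------------------------------------------------------- #

    def _end_constraints(self) -> list[EndConstraint]:
        m = self.mesh
        out = []
        for name, j_plane, j_next in (("inlet_ring", 0, 1), ("outlet_ring", m.n_rings - 1, m.n_rings - 2)):
            ids = m.node_sets[name]
            ring0 = self.X[m.luminal_ring_ids(j_plane)]
            ring1 = self.X[m.luminal_ring_ids(j_next)]
            axis = ring1.mean(axis=0) - ring0.mean(axis=0)
            axis /= np.linalg.norm(axis)
            out.append(EndConstraint(node_ids=ids, axis=axis, origin=ring0.mean(axis=0) * 1e3))
        return out

    def _reduction_matrix(self) -> sp.csr_matrix:
        nn = self.n_nodes
        kind = np.zeros(nn, dtype=int)  # 0 free, 1 radial-only
        radial = np.zeros((nn, 3))
        for ec in self.constraints:
            origin = ec.origin * 1e-3
            for nid in ec.node_ids:
                d = self.X[nid] - origin
                d = d - np.dot(d, ec.axis) * ec.axis
                nrm = np.linalg.norm(d)
                if nrm < 1e-12:
                    continue  # on-axis node: fully fixed
                kind[nid] = 1
                radial[nid] = d / nrm
        rows, cols, vals = [], [], []
        col = 0
        self._free_map = np.full(nn, -1)
        for n in range(nn):
            if kind[n] == 0 and not self._is_end(n):
                for i in range(3):
                    rows.append(3 * n + i)
                    cols.append(col)
                    vals.append(1.0)
                    col += 1
            elif kind[n] == 1:
                for i in range(3):
                    rows.append(3 * n + i)
                    cols.append(col)
                    vals.append(radial[n, i])
                col += 1
        self.n_free = col
        return sp.csr_matrix((vals, (rows, cols)), shape=(3 * nn, col))

    def _is_end(self, n: int) -> bool:
        # nodes in either end set (used only to catch fully fixed on-axis nodes)
        if not hasattr(self, "_end_ids"):
            self._end_ids = set(np.concatenate([ec.node_ids for ec in self.constraints]).tolist())
        return n in self._end_ids

    def _orient_faces(self) -> float:
        """Sign making (x_xi cross x_eta) point outwards (lumen -> wall)."""
        xf = self.X[self.faces]
        g = 4  # centre Gauss point
        xxi = np.einsum("n,fni->fi", FACE_DN[g, :, 0], xf)
        xeta = np.einsum("n,fni->fi", FACE_DN[g, :, 1], xf)
        nvec = np.cross(xxi, xeta)
        centre = np.einsum("n,fni->fi", FACE_N[g], xf)
        m = self.mesh
        ring_cent = self.X[: m.n_rings * m.nodes_per_ring].reshape(m.n_rings, m.nodes_per_ring, 3).mean(axis=1)
        # outward = face centre minus nearest luminal ring centroid
        d2 = ((centre[:, None, :] - ring_cent[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)
        outward = centre - ring_cent[nearest]
        s = np.sign(np.einsum("fi,fi->f", nvec, outward))
        if not (np.all(s > 0) or np.all(s < 0)):
            raise ValueError("inconsistent luminal face orientation")
        return float(s[0])

    # -- pressure field ---------------------------------------------------- #

    def nodal_pressure(self, pressure_mmhg, profile: np.ndarray | None = None) -> np.ndarray:
        """Per-node luminal pressure (Pa) on the full node vector.

        ``profile``: optional per-axial-lattice-plane pressures (mmHg,
        length n_rings) broadcast around each ring; otherwise the scalar
        ``pressure_mmhg`` is applied uniformly.
        """
        m = self.mesh
        p = np.zeros(self.n_nodes)
        lum = m.node_sets["luminal"]
        if profile is not None:
            ring = np.repeat(np.arange(m.n_rings), m.nodes_per_ring)
            p[lum] = np.asarray(profile)[ring] * MMHG_TO_PA
        else:
            p[lum] = pressure_mmhg * MMHG_TO_PA
        return p

    # -- assembly ---------------------------------------------------------- #

    def _kinematics(self, u: np.ndarray):
        ue = u[self.elems]  # (ne, 27, 3)
        F = self._einsum("egnj,eni->egij", self.dNdX, ue)
        F = F + _I3
        J = _det3(F)
        if J.min() <= 0:
            return F, J, None, None
        Finv = _inv3(F, J)
        dNdx = self._einsum("egnk,egkj->egnj", self.dNdX, Finv)
        return F, J, Finv, dNdx

    def _stress(self, F: np.ndarray, J: np.ndarray) -> np.ndarray:
        mu, lam = self.mat.G_pa, self.mat.lame_lambda_pa
        B = self._einsum("egik,egjk->egij", F, F)
        lnJ = np.log(J)
        return (mu / J)[..., None, None] * (B - _I3) + (lam * lnJ / J)[..., None, None] * _I3

    def internal_forces(self, u: np.ndarray, sigma0: np.ndarray | None, tangent: bool = True):
        """Internal force vector (and tangent matrix) at displacement u (m)."""
        use0 = sigma0 is not None
        s0 = sigma0 if use0 else _DUMMY_SIG
        fint, sig, ok = kern.residual_and_stress(
            u, self.elems, self.dNdX, self.detJ0, HEX_W, self.mat.G_pa,
            self.mat.lame_lambda_pa, s0, use0,
        )
        if not ok:
            return None, None, None
        if not tangent:
            return fint.ravel(), None, sig
        K, ok = kern.tangent_blocks(
            u, self.elems, self.dNdX, self.detJ0, HEX_W, self.mat.G_pa,
            self.mat.lame_lambda_pa, s0, use0,
        )
        return fint.ravel(), K, sig

    def external_forces(self, u: np.ndarray, p_nodal: np.ndarray, tangent: bool = True):
        """Follower pressure load vector and its load stiffness."""
        x = self.X + u
        fext = kern.face_forces(
            x, self.faces, p_nodal, FACE_N, FACE_DN, FACE_W, self._face_sign
        ).ravel()
        if not tangent:
            return fext, self._fdof, None
        Kl = kern.face_stiffness(
            x, self.faces, p_nodal, FACE_N, FACE_DN, FACE_W, self._face_sign
        )
        return fext, self._fdof, Kl

    def _assemble_matrix(self, K_el, fdof, Kl_el) -> sp.csr_matrix:
        nn3 = 3 * self.n_nodes
        A = sp.coo_matrix((K_el.ravel(), (self.rows, self.cols)), shape=(nn3, nn3))
        lr = np.repeat(fdof, 27, axis=1).ravel()
        lc = np.tile(fdof, (1, 27)).ravel()
        L = sp.coo_matrix(((-Kl_el).ravel(), (lr, lc)), shape=(nn3, nn3))
        return (A + L).tocsr()

    # -- Newton solve ------------------------------------------------------ #

    def solve(
        self,
        p_nodal: np.ndarray,
        u0: np.ndarray | None = None,
        sigma0: np.ndarray | None = None,
        tol: float = 1e-8,
        max_iter: int = 50,
        reuse_factor: bool = False,
    ) -> tuple[np.ndarray, np.ndarray, list[float]]:
        """Newton iteration on the follower-load equilibrium.

        With ``reuse_factor`` the previous tangent factorization (possibly
        from an earlier solve) is reused until convergence stalls, which makes
        the many small warm-started solves of the FSI loop cheap; the
        converged solution is identical since iteration is residual-driven.

        Returns (displacement (m), gauss Cauchy stress (Pa), residual history).
        """
        u = np.zeros((self.n_nodes, 3)) if u0 is None else u0.copy()
        Tt = self.T.T
        history: list[float] = []
        scale = None
        lu = self._lu if (reuse_factor and self._lu is not None) else None
        age = max_iter  # Newton steps since the current factor was assembled
        growth = 0
        best = None  # (rn, u, sig) fallback for round-off-floor stagnation
        for it in range(max_iter):
            need_tangent = lu is None
            fint, K_el, sig = self.internal_forces(u, sigma0, tangent=need_tangent)
            if fint is None:
                raise ConvergenceError("element inversion during Newton iteration", history)
            fext, fdof, Kl_el = self.external_forces(u, p_nodal, tangent=need_tangent)
            r = Tt @ (fint - fext)
            if scale is None:
                scale = max(np.linalg.norm(Tt @ fext), np.linalg.norm(Tt @ fint), 1e-30)
            rn = np.linalg.norm(r) / scale
            history.append(rn)
            if rn < tol:
                return u, sig, history
            if best is None or rn < best[0]:
                best = (rn, u.copy(), sig)
            growth = growth + 1 if (len(history) >= 2 and rn > history[-2]) else 0
            if growth >= 3 and age <= 3:
                # a fresh tangent could not reduce the residual: either true
                # divergence, or stagnation at the assembly round-off floor
                if best[0] < max(1e3 * tol, 1e-8):
                    return best[1], best[2], history
                raise ConvergenceError(
                    "Newton residual grew over three consecutive iterations "
                    "despite a recent tangent",
                    history,
                )
            # refactor on stall only while still far from tolerance; near the
            # round-off floor extra back-substitutions are cheaper than a new
            # factorization and the best-iterate fallback handles stagnation
            stalled = len(history) >= 2 and rn > 0.25 * history[-2] and rn > 30.0 * tol
            if lu is None or (stalled and age > 0):
                if K_el is None:
                    fint, K_el, sig = self.internal_forces(u, sigma0, tangent=True)
                    fext, fdof, Kl_el = self.external_forces(u, p_nodal, tangent=True)
                A = (Tt @ self._assemble_matrix(K_el, fdof, Kl_el) @ self.T).tocsc()
                lu = spla.splu(A, permc_spec="MMD_ATA")
                self._lu = lu
                age = 0
            du = (self.T @ lu.solve(-r)).reshape(-1, 3)
            age += 1
            # full Newton steps; backtrack only on element inversion (the
            # residual norm is a poor merit function for the stiff penalty)
            alpha = 1.0
            for _ in range(8):
                fint_t, _, _ = self.internal_forces(u + alpha * du, sigma0, tangent=False)
                if fint_t is not None:
                    break
                alpha *= 0.5
            else:
                raise ConvergenceError("line search could not avoid element inversion", history)
            u = u + alpha * du
        if best is not None and best[0] < max(1e3 * tol, 1e-8):
            return best[1], best[2], history
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations (residual {history[-1]:.3e})",
            history,
        )

    def solve_ramped(self, p_nodal, u0=None, sigma0=None, tol=1e-8, max_substeps=8):
        """Solve with automatic load substepping on Newton failure."""
        n_sub = 1
        while True:
            try:
                u = u0
                sig = None
                for k in range(1, n_sub + 1):
                    u, sig, _ = self.solve(p_nodal * (k / n_sub), u0=u, sigma0=sigma0, tol=tol)
                return u, sig
            except ConvergenceError:
                n_sub *= 2
                if n_sub > max_substeps:
                    raise

    # -- helpers ----------------------------------------------------------- #

    def luminal_ring_areas(self, u: np.ndarray) -> np.ndarray:
        """Cross-sectional lumen area (m^2) at every axial lattice plane."""
        m = self.mesh
        x = (self.X + u)[: m.n_rings * m.nodes_per_ring].reshape(m.n_rings, m.nodes_per_ring, 3)
        c = x.mean(axis=1, keepdims=True)
        rel = x - c
        cross = np.cross(rel, np.roll(rel, -1, axis=1))
        return 0.5 * np.linalg.norm(cross.sum(axis=1), axis=1)

    def strain_energy(self, u: np.ndarray) -> float:
        """Stored hyperelastic energy (J) of the penalty material."""
        F, J, Finv, _ = self._kinematics(u)
        if Finv is None:
            raise ValueError("inverted state")
        mu, lam = self.mat.G_pa, self.mat.lame_lambda_pa
        I1 = np.einsum("egij,egij->eg", F, F)
        lnJ = np.log(J)
        W = 0.5 * mu * (I1 - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
        return float(np.sum(W * self.detJ0 * HEX_W[None, :]))


# --------------------------------------------------------------------------- #
# high-level operations (clinical units)
# --------------------------------------------------------------------------- #


def solve_static_inflation(
    mesh: WallMesh,
    mat: Material,
    pressure: float,
    constraints=None,
    initial: WallState | None = None,
    fem: WallFem | None = None,
    pressure_profile: np.ndarray | None = None,
    tol: float = 1e-8,
) -> WallState:
    """Static equilibrium under a luminal follower pressure (mmHg).

    ``initial`` may carry a pre-stress field (from :func:`bim_prestress`) and
    a starting displacement guess.  End cross-sections move radially only.
    """
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    f = fem or WallFem(mesh, mat)
    p_nodal = f.nodal_pressure(pressure, pressure_profile)
    u0 = None
    sigma0 = None
    if initial is not None:
        u0 = initial.displacement * 1e-3
        if initial.prestressed:
            sigma0 = initial.cauchy_stress * 1e3  # kPa -> Pa
    u, sig = f.solve_ramped(p_nodal, u0=u0, sigma0=sigma0, tol=tol)
    return WallState(
        displacement=u * 1e3,
        cauchy_stress=sig * 1e-3,
        applied_pressure=float(pressure),
        prestressed=initial.prestressed if initial is not None else False,
    )


def bim_prestress(
    mesh: WallMesh,
    mat: Material,
    p_m: float,
    i_max: int = 20,
    fem: WallFem | None = None,
    tol: float = 1e-8,
) -> WallState:
    """Backward-incremental pre-stress at measured pressure ``p_m`` (mmHg).

    Pressure schedule p_i = p_m sin(i pi / (2 i_max)); every increment resets
    the nodal positions to the measured geometry and carries the previous
    increment's Cauchy stress as initial stress in a single equilibrium solve.
    """
    if p_m <= 0:
        raise ValueError("measured pressure must be positive")
    f = fem or WallFem(mesh, mat)
    sigma0: np.ndarray | None = None
    for i in range(1, i_max + 1):
        p_i = p_m * np.sin(i * np.pi / (2.0 * i_max))
        p_nodal = f.nodal_pressure(p_i)
        try:
            u, sig, _ = f.solve(p_nodal, u0=None, sigma0=sigma0, tol=tol, reuse_factor=i > 1)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"pre-stress increment {i}/{i_max} (p = {p_i:.2f} mmHg) failed",
                err.residual_history,
                increment=i,
            ) from err
        sigma0 = sig  # total stress, carried onto the reset geometry
    return WallState(
        displacement=np.zeros_like(mesh.nodes),
        cauchy_stress=sigma0 * 1e-3,
        applied_pressure=float(p_m),
        prestressed=True,
    )


def bim_pressure_schedule(p_m: float, i_max: int = 20) -> np.ndarray:
    """The BIM load schedule p_i = p_m sin(i pi / (2 i_max)), i = 1..i_max."""
    i = np.arange(1, i_max + 1)
    return p_m * np.sin(i * np.pi / (2.0 * i_max))
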