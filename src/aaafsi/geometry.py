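"""AAA lumen geometry: synthetic segmentations, elongation, surface and wall meshing.

The geometric ground truth is a stack of planar elliptical contours along a
(possibly curved) centerline, mimicking the output of an ultrasound lumen
segmentation at the diastolic frame.  The stack is elongated with cubic Bezier
extensions to circular 20 mm inlet/outlet sections, resampled into a structured
quadrilateral lumen surface, and extruded into a two-layer triquadratic
hexahedral wall mesh (2 mm nominal thickness).

Coordinates are right-handed with the global z axis longitudinal ("spine"
axis); all lengths in mm; axial stations are arc length from the proximal end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elements import jacobians

MMHG_TO_PA = 133.322  # re-exported convenience

__all__ = [
    "Contour",
    "ContourStack",
    "LumenSurfaceMesh",
    "WallMesh",
    "AaaProfile",
    "generate_synthetic_aaa",
    "elongate_contours",
    "build_lumen_surface",
    "extrude_wall_mesh",
    "max_diameter_and_group",
    "enclosed_lumen_volume",
]


class GeometryError(ValueError):
    """Raised for non-physical or inconsistent geometric input."""


# --------------------------------------------------------------------------- #
# contours
# --------------------------------------------------------------------------- #


@dataclass
class Contour:
    """One planar elliptical lumen contour.

    ``normal`` is the unit centerline tangent at the contour; ``rotation``
    rotates the ellipse axes within the contour plane relative to the
    parallel-transported in-plane frame of the stack.
    """

    center: np.ndarray
    major_radius: float
    minor_radius: float
    normal: np.ndarray
    rotation: float
    axial_station: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if not (self.major_radius >= self.minor_radius > 0.0):
            raise GeometryError(
                f"contour radii must satisfy major >= minor > 0, got "
                f"({self.major_radius}, {self.minor_radius})"
            )
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise GeometryError("contour normal must be a unit vector")

    @property
    def diameter(self) -> float:
        """Maximal in-plane chord (twice the major radius)."""
        return 2.0 * self.major_radius


@dataclass
class ContourStack:
    """Ordered lumen contours along a centerline (diastolic frame)."""

    contours: list[Contour]
    spacing: float
    frame_label: str = "diastole"
    elongated: bool = False
    #: arc-length interval occupied by the native (pre-elongation) geometry
    native_span: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GeometryError("contour spacing must be positive")
        st = self.stations
        if not np.all(np.diff(st) > 0):
            raise GeometryError("axial stations must be strictly increasing")
        if self.elongated:
            for c in (self.contours[0], self.contours[-1]):
                if abs(c.major_radius - c.minor_radius) > 1e-9:
                    raise GeometryError("elongated stack must end in circular contours")

    @property
    def stations(self) -> np.ndarray:
        return np.array([c.axial_station for c in self.contours])

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.contours])

    @property
    def length(self) -> float:
        return float(self.stations[-1] - self.stations[0])

    def frames(self) -> np.ndarray:
        """Parallel-transported in-plane frames, shape (n, 2, 3).

        The first frame seeds from the global x axis projected onto the first
        contour plane; subsequent frames rotate with the minimal rotation
        taking one normal into the next (no spurious twist).
        """
        normals = np.array([c.normal for c in self.contours])
        e1 = np.array([1.0, 0.0, 0.0])
        e1 = e1 - np.dot(e1, normals[0]) * normals[0]
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.array([0.0, 1.0, 0.0])
            e1 = e1 - np.dot(e1, normals[0]) * normals[0]
        e1 /= np.linalg.norm(e1)
        out = np.empty((len(self.contours), 2, 3))
        for i, n in enumerate(normals):
            if i > 0:
                e1 = _rotate_between(normals[i - 1], n) @ e1
                e1 = e1 - np.dot(e1, n) * n
                e1 /= np.linalg.norm(e1)
            out[i, 0] = e1
            out[i, 1] = np.cross(n, e1)
        return out

    def sample_points(self, n_theta: int) -> np.ndarray:
        """Ring points for every contour, shape (n_contours, n_theta, 3)."""
        frames = self.frames()
        theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
        pts = np.empty((len(self.contours), n_theta, 3))
        for i, c in enumerate(self.contours):
            u1 = np.cos(c.rotation) * frames[i, 0] + np.sin(c.rotation) * frames[i, 1]
            u2 = -np.sin(c.rotation) * frames[i, 0] + np.cos(c.rotation) * frames[i, 1]
            pts[i] = (
                c.center
                + c.major_radius * np.cos(theta)[:, None] * u1
                + c.minor_radius * np.sin(theta)[:, None] * u2
            )
        return pts


def _rotate_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-14:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


# --------------------------------------------------------------------------- #
# synthetic segmentation generator
# --------------------------------------------------------------------------- #


@dataclass
class AaaProfile:
    """Shape parameters of the synthetic fusiform AAA segmentation.

    Defaults emulate a moderate aneurysm near the cohort average: 47 mm
    maximum diameter, 22 mm necks, 7.5 cm sac, with sub-voxel segmentation
    jitter.  The pronounced cross-sectional asymmetry and anterior centerline
    bow reflect how AAAs actually grow: the spine blocks posterior expansion,
    so the sac bulges anteriorly and the centerline bows with it.
    """

    max_diameter: float = 47.0
    neck_diameter: float = 22.0
    sac_length: float = 75.0
    asymmetry: float = 0.40
    centerline_bow: float = 15.0
    n_contours: int = 40
    noise_sd: float = 0.15


def generate_synthetic_aaa(profile: AaaProfile | None = None, seed: int = 0) -> ContourStack:
    """Generate a synthetic diastolic AAA contour stack.

    Deterministic for a fixed ``seed``; raises :class:`GeometryError` for
    non-physical profiles (``max_diameter <= neck_diameter``).
    """
    p = profile or AaaProfile()
    if not (p.max_diameter > p.neck_diameter > 0.0):
        raise GeometryError("profile requires max_diameter > neck_diameter > 0")
    if p.n_contours < 5:
        raise GeometryError("profile requires n_contours >= 5")
    rng = np.random.default_rng(seed)
    L = float(p.sac_length)
    u = np.linspace(0.0, L, p.n_contours)

    # fusiform diameter bump centred on the sac
    w = np.exp(-(((u - L / 2.0) / (L / 4.5)) ** 2))
    diam = p.neck_diameter + (p.max_diameter - p.neck_diameter) * w

    # bowed centerline in the x-z plane; z is the spine axis
    x = p.centerline_bow * np.sin(np.pi * u / L)
    centers = np.column_stack([x, np.zeros_like(u), u])
    dx = p.centerline_bow * np.pi / L * np.cos(np.pi * u / L)
    tangents = np.column_stack([dx, np.zeros_like(u), np.ones_like(u)])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    major = diam / 2.0
    minor = major * (1.0 - p.asymmetry * w)
    # anterior shift of the dilated cross-sections
    centers[:, 0] += 0.5 * p.asymmetry * (diam - p.neck_diameter) * w

    if p.noise_sd > 0:
        centers[:, :2] += rng.normal(0.0, p.noise_sd, size=(p.n_contours, 2))
        major = major + rng.normal(0.0, p.noise_sd, size=p.n_contours)
        minor = minor + rng.normal(0.0, p.noise_sd, size=p.n_contours)
    minor = np.clip(minor, 0.25 * p.neck_diameter, None)
    major = np.maximum(major, minor)

    # arc-length stations along the (noise-free) centerline
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    stations = np.concatenate([[0.0], np.cumsum(seg)])

    contours = [
        Contour(centers[i], float(major[i]), float(minor[i]), tangents[i], 0.0, float(stations[i]))
        for i in range(p.n_contours)
    ]
    return ContourStack(
        contours=contours,
        spacing=float(np.mean(seg)),
        native_span=(0.0, float(stations[-1])),
    )


# --------------------------------------------------------------------------- #
# elongation
# --------------------------------------------------------------------------- #


def _bezier(b: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t)[:, None]
    return (
        (1 - t) ** 3 * b[0]
        + 3 * (1 - t) ** 2 * t * b[1]
        + 3 * (1 - t) * t**2 * b[2]
        + t**3 * b[3]
    )


def _bezier_arc_length(b: np.ndarray, n: int = 400) -> float:
    pts = _bezier(b, np.linspace(0.0, 1.0, n))
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _extension_contours(
    end: Contour,
    outward_tangent: np.ndarray,
    terminal_dir: np.ndarray,
    length: float,
    end_radius: float,
    spacing: float,
) -> list[Contour]:
    """Contours of one cubic-Bezier extension, ordered from the junction outwards.

    The Bezier starts at the junction with the native end tangent (G1) and
    finishes on a straight segment along ``terminal_dir``; radii and rotation
    blend linearly in normalized arc length down to a circle of
    ``end_radius``.
    """
    t0 = outward_tangent / np.linalg.norm(outward_tangent)
    td = terminal_dir / np.linalg.norm(terminal_dir)
    if np.dot(t0, td) < 1e-3:
        raise GeometryError(
            "native end tangent is orthogonal to (or opposes) the requested extension direction"
        )

    def control(chord: float) -> np.ndarray:
        b0 = end.center
        b3 = end.center + chord * td
        return np.array([b0, b0 + (chord / 3.0) * t0, b3 - (chord / 3.0) * td, b3])

    # arc length grows monotonically with the chord scale; bisect to 'length'
    lo, hi = 0.5 * length, 1.5 * length
    while _bezier_arc_length(control(hi)) < length:
        hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _bezier_arc_length(control(mid)) < length:
            lo = mid
        else:
            hi = mid
    b = control(0.5 * (lo + hi))

    # equal-arc-length parameter samples
    n_dense = 800
    tt = np.linspace(0.0, 1.0, n_dense)
    pts = _bezier(b, tt)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    n_ext = max(2, int(np.ceil(length / spacing)))
    s_targets = np.linspace(0.0, s[-1], n_ext + 1)[1:]  # skip the junction itself
    t_samples = np.interp(s_targets, s, tt)

    # tangents of the Bezier (pointing outwards)
    db = 3 * (
        (1 - t_samples[:, None]) ** 2 * (b[1] - b[0])
        + 2 * (1 - t_samples[:, None]) * t_samples[:, None] * (b[2] - b[1])
        + t_samples[:, None] ** 2 * (b[3] - b[2])
    )
    db /= np.linalg.norm(db, axis=1, keepdims=True)
    centers = _bezier(b, t_samples)

    frac = s_targets / s[-1]
    majors = end.major_radius + frac * (end_radius - end.major_radius)
    minors = end.minor_radius + frac * (end_radius - end.minor_radius)
    rots = end.rotation * (1.0 - frac)
    out = []
    for i in range(n_ext):
        out.append(
            Contour(
                centers[i],
                float(max(majors[i], minors[i])),
                float(min(majors[i], minors[i])),
                db[i],
                float(rots[i]),
                float(s_targets[i]),  # provisional; stack re-stations later
            )
        )
    # exact circular terminal contour
    out[-1] = replace(out[-1], major_radius=end_radius, minor_radius=end_radius)
    return out


def elongate_contours(
    stack: ContourStack, length: float = 50.0, end_diameter: float = 20.0
) -> ContourStack:
    """Extend the segmentation by ``length`` mm proximally and distally.

    The proximal extension runs antiparallel to the spine (global z) axis,
    the distal extension along the local centerline direction; both end in
    circular contours of ``end_diameter``.
    """
    if len(stack.contours) < 2:
        raise GeometryError("elongation requires at least two contours")
    first, last = stack.contours[0], stack.contours[-1]
    end_radius = end_diameter / 2.0

    prox = _extension_contours(
        first,
        outward_tangent=-first.normal,
        terminal_dir=np.array([0.0, 0.0, -1.0]),
        length=length,
        end_radius=end_radius,
        spacing=stack.spacing,
    )
    dist = _extension_contours(
        last,
        outward_tangent=last.normal,
        terminal_dir=last.normal,
        length=length,
        end_radius=end_radius,
        spacing=stack.spacing,
    )

    contours: list[Contour] = []
    # proximal contours come out junction->outwards; flip, and flip normals to
    # keep all normals pointing distally
    for c in reversed(prox):
        contours.append(replace(c, normal=-c.normal))
    contours.extend(stack.contours)
    contours.extend(dist)

    # re-station by cumulative arc length of the centers polyline
    centers = np.array([c.center for c in contours])
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    stations = np.concatenate([[0.0], np.cumsum(seg)])
    contours = [replace(c, axial_station=float(s)) for c, s in zip(contours, stations)]

    prox_len = stations[len(prox)]
    native_len = stations[len(prox) + len(stack.contours) - 1] - prox_len
    return ContourStack(
        contours=contours,
        spacing=stack.spacing,
        frame_label=stack.frame_label,
        elongated=True,
        native_span=(float(prox_len), float(prox_len + native_len)),
    )


# --------------------------------------------------------------------------- #
# surface meshing
# --------------------------------------------------------------------------- #


@dataclass
class LumenSurfaceMesh:
    """Structured quadrilateral lumen surface: rings of a shared node count."""

    nodes: np.ndarray  # (n_rings * nodes_per_ring, 3)
    quads: np.ndarray  # (n_quads, 4) int
    ring_index: np.ndarray  # (n_nodes,) int
    n_rings: int
    nodes_per_ring: int
    target_edge: float
    ring_stations: np.ndarray  # (n_rings,) arc length
    native_span: tuple[float, float] = (0.0, 0.0)

    def with_nodes(self, nodes: np.ndarray) -> "LumenSurfaceMesh":
        return replace(self, nodes=np.asarray(nodes, dtype=float))

    def ring_nodes(self, r: int) -> np.ndarray:
        m = self.nodes_per_ring
        return self.nodes[r * m : (r + 1) * m]


def _resample_stack(stack: ContourStack, stations_new: np.ndarray) -> ContourStack:
    """Linear reinterpolation of contour parameters at new arc-length stations."""
    st = stack.stations
    centers = stack.centers
    majors = np.array([c.major_radius for c in stack.contours])
    minors = np.array([c.minor_radius for c in stack.contours])
    rots = np.array([c.rotation for c in stack.contours])
    normals = np.array([c.normal for c in stack.contours])
    out = []
    for s in stations_new:
        ctr = np.array([np.interp(s, st, centers[:, k]) for k in range(3)])
        nrm = np.array([np.interp(s, st, normals[:, k]) for k in range(3)])
        nrm /= np.linalg.norm(nrm)
        ma = float(np.interp(s, st, majors))
        mi = float(np.interp(s, st, minors))
        out.append(Contour(ctr, max(ma, mi), min(ma, mi), nrm, float(np.interp(s, st, rots)), float(s)))
    return ContourStack(
        contours=out,
        spacing=float(np.mean(np.diff(stations_new))),
        frame_label=stack.frame_label,
        elongated=stack.elongated,
        native_span=stack.native_span,
    )


def build_lumen_surface(stack: ContourStack, target_edge: float = 0.8) -> LumenSurfaceMesh:
    """Resample the stack into a structured quad surface with ~``target_edge`` mm edges.

    The circumferential node count is even (required by the quadratic wall
    extrusion) and shared across all rings; the ring count is odd for the same
    reason.  Fails if any contour is too small to carry eight circumferential
    nodes at the requested edge length.
    """
    if len(stack.contours) < 2:
        raise GeometryError("surface meshing requires at least two contours")
    perims = np.array(
        [_ellipse_perimeter(c.major_radius, c.minor_radius) for c in stack.contours]
    )
    if perims.min() / target_edge < 8.0 - 1e-9:
        raise GeometryError(
            f"smallest contour (perimeter {perims.min():.2f} mm) cannot carry "
            f">= 8 circumferential nodes at edge {target_edge} mm"
        )
    m = int(round(np.median(perims) / target_edge / 2.0)) * 2
    m = max(8, m)

    total = stack.length
    n_rings = int(round(total / target_edge)) + 1
    if n_rings % 2 == 0:
        n_rings += 1
    n_rings = max(5, n_rings)
    stations_new = np.linspace(stack.stations[0], stack.stations[-1], n_rings)
    resampled = _resample_stack(stack, stations_new)
    rings = resampled.sample_points(m)  # (n_rings, m, 3)

    nodes = rings.reshape(-1, 3)
    ring_index = np.repeat(np.arange(n_rings), m)
    quads = []
    for r in range(n_rings - 1):
        base = r * m
        for k in range(m):
            k2 = (k + 1) % m
            quads.append([base + k, base + k2, base + m + k2, base + m + k])
    quads = np.array(quads, dtype=int)

    surf = LumenSurfaceMesh(
        nodes=nodes,
        quads=quads,
        ring_index=ring_index,
        n_rings=n_rings,
        nodes_per_ring=m,
        target_edge=target_edge,
        ring_stations=stations_new - stations_new[0],
        native_span=stack.native_span,
    )
    # orient quads outward (normal away from ring centroid)
    if _mean_normal_alignment(surf) < 0:
        surf.quads = surf.quads[:, ::-1].copy()
    return surf


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation."""
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def surface_quad_normals(surf: LumenSurfaceMesh) -> np.ndarray:
    """Unit normals of every quad (cross product of the diagonals)."""
    x = surf.nodes[surf.quads]
    n = np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 1])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def _mean_normal_alignment(surf: LumenSurfaceMesh) -> float:
    normals = surface_quad_normals(surf)
    centroids = surf.nodes[surf.quads].mean(axis=1)
    m = surf.nodes_per_ring
    ring_cent = surf.nodes.reshape(surf.n_rings, m, 3).mean(axis=1)
    quad_ring = surf.ring_index[surf.quads[:, 0]]
    outward = centroids - 0.5 * (ring_cent[quad_ring] + ring_cent[quad_ring + 1])
    return float(np.mean(np.sum(normals * outward, axis=1)))


# --------------------------------------------------------------------------- #
# wall extrusion
# --------------------------------------------------------------------------- #


@dataclass
class WallMesh:
    """Two-layer 27-node hexahedral wall mesh extruded from the lumen surface.

    The node lattice is (circumferential i, axial ring j, thickness sheet k)
    with id ``(k * n_rings + j) * m + i``; quadratic elements span two lattice
    intervals in every direction.
    """

    nodes: np.ndarray  # (n_nodes, 3) mm
    hex_elements: np.ndarray  # (n_elem, 27) int
    node_sets: dict[str, np.ndarray]
    thickness: float
    n_rings: int
    nodes_per_ring: int
    n_sheets: int
    ring_stations: np.ndarray
    native_span: tuple[float, float]
    surface: LumenSurfaceMesh = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def node_id(self, i: np.ndarray, j: np.ndarray, k: np.ndarray) -> np.ndarray:
        return (k * self.n_rings + j) * self.nodes_per_ring + i

    def luminal_ring_ids(self, j: int) -> np.ndarray:
        """Node ids of the luminal (sheet 0) ring at axial lattice plane j."""
        m = self.nodes_per_ring
        return np.arange(j * m, (j + 1) * m)


def _nodal_outward_normals(surf: LumenSurfaceMesh) -> np.ndarray:
    qn = surface_quad_normals(surf)
    normals = np.zeros_like(surf.nodes)
    for corner in range(4):
        np.add.at(normals, surf.quads[:, corner], qn)
    # end rings touch only one strip of quads; still well defined
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return normals


def extrude_wall_mesh(
    surface: LumenSurfaceMesh, thickness: float = 2.0, layers: int = 2
) -> WallMesh:
    """Extrude the lumen surface outward into ``layers`` quadratic hex layers."""
    if surface.n_rings % 2 == 0 or surface.nodes_per_ring % 2 != 0:
        raise GeometryError("quadratic extrusion needs an odd ring count and even ring size")
    m, nr = surface.nodes_per_ring, surface.n_rings
    n_sheets = 2 * layers + 1
    normals = _nodal_outward_normals(surface)
    offsets = np.linspace(0.0, thickness, n_sheets)
    nodes = np.concatenate([surface.nodes + normals * t for t in offsets], axis=0)

    mel, nel = m // 2, (nr - 1) // 2
    elems = np.empty((mel * nel * layers, 27), dtype=int)
    e = 0
    for el in range(layers):
        for ej in range(nel):
            for ei in range(mel):
                conn = np.empty(27, dtype=int)
                for c in range(3):
                    for b in range(3):
                        for a in range(3):
                            i = (2 * ei + a) % m
                            j = 2 * ej + b
                            k = 2 * el + c
                            conn[a + 3 * b + 9 * c] = (k * nr + j) * m + i
                elems[e] = conn
                e += 1

    npr = m * nr
    luminal = np.arange(npr)
    outer = np.arange((n_sheets - 1) * npr, n_sheets * npr)
    sheets = np.arange(n_sheets)
    inlet = (sheets[:, None] * nr * m + np.arange(m)[None, :]).ravel()
    outlet = (sheets[:, None] * nr * m + (nr - 1) * m + np.arange(m)[None, :]).ravel()

    mesh = WallMesh(
        nodes=nodes,
        hex_elements=elems,
        node_sets={
            "luminal": luminal,
            "outer": outer,
            "inlet_ring": inlet,
            "outlet_ring": outlet,
        },
        thickness=float(thickness),
        n_rings=nr,
        nodes_per_ring=m,
        n_sheets=n_sheets,
        ring_stations=surface.ring_stations,
        native_span=surface.native_span,
        surface=surface,
    )
    detj = jacobians(nodes[elems])
    if detj.min() <= 0:
        raise GeometryError(
            "extrusion produced inverted elements (negative Jacobian); the surface "
            "is too concave for the requested thickness"
        )
    return mesh


# --------------------------------------------------------------------------- #
# diagnostics
# --------------------------------------------------------------------------- #


def max_diameter_and_group(stack: ContourStack) -> dict:
    """Maximum in-plane chord over the stack and the S/M/L size group.

    Groups: small <= 39 mm, moderate 40-49 mm, large >= 50 mm.
    """
    d_max = max(c.diameter for c in stack.contours)
    if d_max < 39.5:
        group = "S"
    elif d_max < 49.5:
        group = "M"
    else:
        group = "L"
    return {"d_max": float(d_max), "group": group}


def enclosed_lumen_volume(surface: LumenSurfaceMesh) -> float:
    """Volume enclosed by the lumen surface with planar end caps (mm^3).

    Divergence theorem over oriented triangles: each quad is split along a
    diagonal and the two end rings are fan-triangulated from their centroids.
    A negative signed volume indicates flipped orientation and is rejected.
    """
    tris = []
    q = surface.quads
    tris.append(np.stack([q[:, 0], q[:, 1], q[:, 2]], axis=1))
    tris.append(np.stack([q[:, 0], q[:, 2], q[:, 3]], axis=1))
    tri_idx = np.concatenate(tris, axis=0)
    x = surface.nodes
    v = np.einsum("ti,ti->t", x[tri_idx[:, 0]], np.cross(x[tri_idx[:, 1]], x[tri_idx[:, 2]]))
    vol = v.sum() / 6.0

    m = surface.nodes_per_ring
    for ring, flip in ((0, True), (surface.n_rings - 1, False)):
        ring_pts = surface.ring_nodes(ring)
        cent = ring_pts.mean(axis=0)
        a = ring_pts
        b = np.roll(ring_pts, -1, axis=0)
        if flip:
            a, b = b, a
        vol += np.einsum("ti,ti->t", np.broadcast_to(cent, a.shape), np.cross(a, b)).sum() / 6.0

    if vol <= 0:
        raise GeometryError("signed enclosed volume is non-positive: surface orientation flipped")
    return float(vol)
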