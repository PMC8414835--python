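"""Geometry: synthetic stacks, elongation, surface meshing, wall extrusion."""

import numpy as np
import pytest

from aaafsi import geometry as geo
from aaafsi.elements import jacobians

from conftest import make_tube_stack


class TestSyntheticGenerator:
    def test_max_diameter_matches_profile(self):
        prof = geo.AaaProfile(max_diameter=27.0, noise_sd=0.15)
        stack = geo.generate_synthetic_aaa(prof, seed=1)
        d = geo.max_diameter_and_group(stack)["d_max"]
        assert abs(d - 27.0) <= prof.noise_sd

    def test_deterministic_for_fixed_seed(self):
        prof = geo.AaaProfile()
        a = geo.generate_synthetic_aaa(prof, seed=7)
        b = geo.generate_synthetic_aaa(prof, seed=7)
        for ca, cb in zip(a.contours, b.contours):
            assert np.array_equal(ca.center, cb.center)
            assert ca.major_radius == cb.major_radius
            assert ca.minor_radius == cb.minor_radius

    def test_noise_free_symmetric_profile_is_circular_and_straight(self):
        prof = geo.AaaProfile(asymmetry=0.0, centerline_bow=0.0, noise_sd=0.0)
        stack = geo.generate_synthetic_aaa(prof, seed=0)
        for c in stack.contours:
            assert c.major_radius == pytest.approx(c.minor_radius)
            assert c.center[0] == pytest.approx(0.0)
            assert c.center[1] == pytest.approx(0.0)
            assert np.allclose(c.normal, [0, 0, 1])

    def test_rejects_non_physical_profile(self):
        with pytest.raises(geo.GeometryError):
            geo.generate_synthetic_aaa(geo.AaaProfile(max_diameter=20.0, neck_diameter=22.0))
        with pytest.raises(geo.GeometryError):
            geo.generate_synthetic_aaa(geo.AaaProfile(n_contours=3))


class TestElongation:
    def test_ends_are_20mm_circles_and_length_grows_100mm(self):
        stack = geo.generate_synthetic_aaa(geo.AaaProfile(), seed=2)
        el = geo.elongate_contours(stack)
        assert el.contours[0].diameter == pytest.approx(20.0)
        assert el.contours[-1].diameter == pytest.approx(20.0)
        assert el.contours[0].major_radius == pytest.approx(el.contours[0].minor_radius)
        assert el.length == pytest.approx(stack.length + 100.0, abs=0.3)

    def test_straight_20mm_tube_elongates_to_straight_tube(self):
        stack = make_tube_stack(radius=10.0, length=50.0, n=11)
        el = geo.elongate_contours(stack)
        for c in el.contours:
            assert c.major_radius == pytest.approx(10.0, abs=1e-9)
            assert abs(c.center[0]) < 1e-9 and abs(c.center[1]) < 1e-9
        assert el.length == pytest.approx(150.0, abs=1e-6)

    def test_tangent_continuity_at_junctions(self):
        stack = geo.generate_synthetic_aaa(
            geo.AaaProfile(centerline_bow=12.0, noise_sd=0.0), seed=3
        )
        el = geo.elongate_contours(stack)
        n_prox = len(el.contours) - len(stack.contours) - sum(
            1 for c in el.contours if c.axial_station > el.native_span[1] + 1e-9
        )
        centers = el.centers
        seg = np.diff(centers, axis=0)
        seg /= np.linalg.norm(seg, axis=1, keepdims=True)
        cosangles = np.einsum("ij,ij->i", seg[:-1], seg[1:])
        # direction change across the two junctions stays small (G1)
        for j in (n_prox - 1, n_prox, len(el.contours) - len(stack.contours) + n_prox - 2):
            assert cosangles[max(0, min(j, len(cosangles) - 1))] > 0.995

    def test_re_elongation_adds_straight_circular_segments_only(self):
        stack = make_tube_stack(radius=10.0, length=50.0, n=11)
        once = geo.elongate_contours(stack)
        twice = geo.elongate_contours(once)
        n_new = len(twice.contours) - len(once.contours)
        added = twice.contours[: n_new // 2] + twice.contours[len(twice.contours) - n_new // 2 :]
        for c in added:
            assert c.major_radius == pytest.approx(10.0, abs=1e-9)
            assert c.minor_radius == pytest.approx(10.0, abs=1e-9)
            assert abs(c.center[0]) < 1e-9 and abs(c.center[1]) < 1e-9

    def test_native_span_tracks_the_original_geometry(self):
        stack = geo.generate_synthetic_aaa(geo.AaaProfile(), seed=4)
        el = geo.elongate_contours(stack)
        lo, hi = el.native_span
        assert lo == pytest.approx(50.0, abs=0.5)
        assert hi - lo == pytest.approx(stack.length, abs=0.5)


class TestLumenSurface:
    def test_quad_count_and_ring_topology(self):
        stack = make_tube_stack()
        surf = geo.build_lumen_surface(stack, target_edge=2.0)
        n, m = surf.n_rings, surf.nodes_per_ring
        assert len(surf.quads) == (n - 1) * m
        assert m % 2 == 0 and n % 2 == 1

    def test_circumferential_node_count_follows_arc_length(self):
        surf = geo.build_lumen_surface(make_tube_stack(radius=10.0), target_edge=0.8)
        # 2 pi 10 / 0.8 ~ 78.5 -> nearest even count
        assert surf.nodes_per_ring == 78

    def test_median_edge_close_to_target(self):
        stack = geo.elongate_contours(geo.generate_synthetic_aaa(geo.AaaProfile(), seed=5))
        surf = geo.build_lumen_surface(stack, target_edge=4.0)
        x = surf.nodes[surf.quads]
        edges = np.linalg.norm(np.roll(x, -1, axis=1) - x, axis=2).ravel()
        assert abs(np.median(edges) - 4.0) / 4.0 < 0.2

    def test_normals_point_outward(self):
        surf = geo.build_lumen_surface(make_tube_stack(), target_edge=2.0)
        normals = geo.surface_quad_normals(surf)
        centroids = surf.nodes[surf.quads].mean(axis=1)
        outward = centroids - np.array([0.0, 0.0, 1.0]) * centroids[:, 2:]
        assert np.all(np.einsum("ij,ij->i", normals, outward) > 0)

    def test_too_small_contour_rejected(self):
        with pytest.raises(geo.GeometryError):
            geo.build_lumen_surface(make_tube_stack(radius=1.0), target_edge=0.8)


class TestWallExtrusion:
    def test_hex_count_is_twice_quad_count(self):
        surf = geo.build_lumen_surface(make_tube_stack(length=40.0, n=9), target_edge=4.0)
        mesh = geo.extrude_wall_mesh(surf, thickness=2.0, layers=2)
        assert mesh.hex_elements.shape[0] == 2 * len(surf.quads) // 4
        # 27-node hexes span 2x2 quads: count against the element grid instead
        mel, nel = surf.nodes_per_ring // 2, (surf.n_rings - 1) // 2
        assert mesh.hex_elements.shape[0] == mel * nel * 2

    def test_straight_tube_outer_radius(self):
        surf = geo.build_lumen_surface(make_tube_stack(), target_edge=2.0)
        mesh = geo.extrude_wall_mesh(surf, thickness=2.0)
        outer = np.linalg.norm(mesh.nodes[mesh.node_sets["outer"]][:, :2], axis=1)
        assert np.allclose(outer, 12.0, atol=1e-6)

    def test_wall_volume_matches_annulus(self):
        surf = geo.build_lumen_surface(make_tube_stack(), target_edge=1.0)
        mesh = geo.extrude_wall_mesh(surf, thickness=2.0)
        detj = jacobians(mesh.nodes[mesh.hex_elements])
        from aaafsi.elements import HEX_W
        vol = float(np.sum(detj * HEX_W[None, :]))
        exact = np.pi * (12.0**2 - 10.0**2) * 100.0
        assert abs(vol - exact) / exact < 0.01

    def test_node_sets_and_sheet_structure(self):
        surf = geo.build_lumen_surface(make_tube_stack(length=40.0, n=9), target_edge=4.0)
        mesh = geo.extrude_wall_mesh(surf)
        npr = surf.n_rings * surf.nodes_per_ring
        assert mesh.n_sheets == 5
        assert len(mesh.node_sets["luminal"]) == npr
        assert len(mesh.node_sets["outer"]) == npr
        assert len(mesh.node_sets["inlet_ring"]) == 5 * surf.nodes_per_ring

    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixtures_yield_valid_meshes(self, seed):
        stack = geo.generate_synthetic_aaa(geo.AaaProfile(n_contours=25), seed=seed)
        surf = geo.build_lumen_surface(geo.elongate_contours(stack), target_edge=7.0)
        mesh = geo.extrude_wall_mesh(surf)
        detj = jacobians(mesh.nodes[mesh.hex_elements])
        assert detj.min() > 0
        # local thickness within 5% of nominal
        lum = mesh.nodes[mesh.node_sets["luminal"]]
        out = mesh.nodes[mesh.node_sets["outer"]]
        th = np.linalg.norm(out - lum, axis=1)
        assert np.all(np.abs(th - 2.0) < 0.1)


class TestDiameterGrouping:
    @pytest.mark.parametrize(
        "d,expected", [(39.0, "S"), (40.0, "M"), (49.0, "M"), (50.0, "L"), (20.0, "S"), (56.0, "L")]
    )
    def test_group_cutoffs(self, d, expected):
        stack = make_tube_stack(radius=d / 2.0, length=30.0, n=5)
        out = geo.max_diameter_and_group(stack)
        assert out["d_max"] == pytest.approx(d)
        assert out["group"] == expected


class TestEnclosedVolume:
    def test_cylinder_volume(self):
        surf = geo.build_lumen_surface(make_tube_stack(), target_edge=0.8)
        vol = geo.enclosed_lumen_volume(surf)
        assert abs(vol - np.pi * 1e4) / (np.pi * 1e4) < 0.005

    def test_sphere_volume(self):
        zs = np.linspace(-9.8, 9.8, 61)
        contours = [
            geo.Contour(
                np.array([0.0, 0.0, z]),
                float(np.sqrt(10.0**2 - z**2)),
                float(np.sqrt(10.0**2 - z**2)),
                np.array([0.0, 0.0, 1.0]),
                0.0,
                float(z),
            )
            for z in zs
        ]
        stack = geo.ContourStack(contours, spacing=float(zs[1] - zs[0]))
        surf = geo.build_lumen_surface(stack, target_edge=0.8)
        vol = geo.enclosed_lumen_volume(surf)
        exact = 4.0 / 3.0 * np.pi * 1000.0
        assert abs(vol - exact) / exact < 0.01

    def test_flipped_orientation_rejected(self):
        surf = geo.build_lumen_surface(make_tube_stack(), target_edge=2.0)
        flipped = surf.with_nodes(surf.nodes)
        flipped.quads = surf.quads[:, ::-1].copy()
        with pytest.raises(geo.GeometryError):
            geo.enclosed_lumen_volume(flipped)

    def test_refinement_shrinks_volume_error(self):
        exact = np.pi * 1e4
        errs = []
        for edge in (3.2, 1.6, 0.8):
            surf = geo.build_lumen_surface(make_tube_stack(), target_edge=edge)
            errs.append(abs(geo.enclosed_lumen_volume(surf) - exact))
        assert errs[1] < errs[0] and errs[2] < errs[1]
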