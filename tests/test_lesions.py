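import numpy as np
import pytest
from oracle_geometry import brute_force_signed_distance, random_star_ring

from mpjunction import (GAFocus, InvalidGeometryError, LesionTracing, NoLesionError, ZoneSpec,
                        filter_min_area, polygon_area, signed_distance, signed_distances,
                        zone_membership)
from mpjunction.simulate import LesionModel, SimulationConfig, simulate_lesion

SQUARE = GAFocus([[0, 0], [1000, 0], [1000, 1000], [0, 1000]], "sq")


def star_ring(rng, center, radius):
    return random_star_ring(rng, center, radius)


class TestPolygonArea:
    def test_unit_square_mm2(self):
        assert polygon_area(SQUARE) == pytest.approx(1.0)

    def test_triangle_half_mm2(self):
        tri = GAFocus([[0, 0], [1000, 0], [0, 1000]], "tri")
        assert polygon_area(tri) == pytest.approx(0.5)

    def test_orientation_invariance(self):
        rev = GAFocus(SQUARE.vertices_um[::-1], "rev")
        assert polygon_area(rev) == polygon_area(SQUARE)

    @pytest.mark.parametrize("verts", [
        [[0, 0], [1, 1]],                          # < 3 vertices
        [[0, 0], [1000, 1000], [1000, 0], [0, 1000]],  # bow-tie self-intersection
        [[0, 0], [500, 0], [1000, 0]],             # zero area
    ])
    def test_degenerate_polygons_rejected(self, verts):
        with pytest.raises(InvalidGeometryError):
            GAFocus(verts, "bad")


class TestMinAreaFilter:
    def _tracing(self, areas_mm2, threshold=0.05):
        foci = []
        for i, a in enumerate(areas_mm2):
            side = np.sqrt(a) * 1000.0
            foci.append(GAFocus([[0, 0], [side, 0], [side, side], [0, side]] +
                                np.array([3000.0 * i, 0.0]), f"F{i}"))
        return LesionTracing(foci, "eye", min_focus_area_mm2=threshold)

    def test_subthreshold_focus_dropped(self):
        out = filter_min_area(self._tracing([0.04, 0.06]))
        assert [f.focus_id for f in out.foci] == ["F1"]

    def test_all_below_threshold_gives_empty_tracing(self):
        out = filter_min_area(self._tracing([0.01, 0.02]))
        assert len(out) == 0
        with pytest.raises(NoLesionError):
            signed_distance([0.0, 0.0], out)

    def test_zero_threshold_keeps_all(self):
        assert len(filter_min_area(self._tracing([0.01, 0.5], threshold=0.0))) == 2


class TestSignedDistance:
    def test_center_of_square_is_minus_500(self):
        tr = LesionTracing([SQUARE], "eye")
        assert signed_distance([500.0, 500.0], tr).distance_um == pytest.approx(-500.0)

    def test_exterior_point_positive(self):
        tr = LesionTracing([SQUARE], "eye")
        assert signed_distance([1500.0, 500.0], tr).distance_um == pytest.approx(500.0)

    def test_on_margin_zero_with_nonnegative_sign(self):
        tr = LesionTracing([SQUARE], "eye")
        d = signed_distance([1000.0, 500.0], tr).distance_um
        assert d == 0.0 and not np.signbit(d)

    def test_nearest_focus_attribution(self):
        far = GAFocus(SQUARE.vertices_um + np.array([5000.0, 0.0]), "far")
        tr = LesionTracing([SQUARE, far], "eye")
        assert signed_distance([1200.0, 500.0], tr).nearest_focus_id == "sq"
        assert signed_distance([4800.0, 500.0], tr).nearest_focus_id == "far"

    def test_nested_foci_even_odd_rule(self):
        outer = GAFocus([[0, 0], [4000, 0], [4000, 4000], [0, 4000]], "outer")
        inner = GAFocus([[1500, 1500], [2500, 1500], [2500, 2500], [1500, 2500]], "inner")
        tr = LesionTracing([outer, inner], "eye")
        # center is inside both rings → even count → spared island, positive sign
        assert signed_distance([2000.0, 2000.0], tr).distance_um == pytest.approx(500.0)
        # between the rings → inside one ring only → atrophic, negative
        assert signed_distance([750.0, 2000.0], tr).distance_um == pytest.approx(-750.0)

    def test_homogeneity_under_scaling(self, rng):
        ring = star_ring(rng, np.array([0.0, 0.0]), 800.0)
        p = rng.uniform(-1500, 1500, 2)
        d1 = signed_distance(p, LesionTracing([GAFocus(ring, "f")], "e")).distance_um
        k = 3.7
        d2 = signed_distance(p * k, LesionTracing([GAFocus(ring * k, "f")], "e")).distance_um
        assert d2 == pytest.approx(k * d1, rel=1e-9)

    def test_vertex_distance_upper_bound(self, rng):
        ring = star_ring(rng, np.zeros(2), 600.0)
        tr = LesionTracing([GAFocus(ring, "f")], "e")
        for p in rng.uniform(-2000, 2000, (25, 2)):
            d = abs(signed_distance(p, tr).distance_um)
            assert d <= np.min(np.linalg.norm(ring - p, axis=1)) + 1e-9

    def test_matches_brute_force_oracle_on_multifocal_tracings(self, rng):
        """Implementation vs dense-boundary-sampling + ray-casting oracle."""
        for _ in range(25):
            rings = [star_ring(rng, rng.uniform(-2000, 2000, 2), rng.uniform(300, 900))
                     for _ in range(int(rng.integers(1, 4)))]
            tr = LesionTracing([GAFocus(r, f"f{i}") for i, r in enumerate(rings)], "e",
                               min_focus_area_mm2=0.0)
            pts = rng.uniform(-3000, 3000, (4, 2))
            results = signed_distances(pts, tr)
            for p, res in zip(pts, results):
                # compare against the normalized (CCW) rings actually stored
                stored = [f.vertices_um for f in tr.foci]
                oracle = brute_force_signed_distance(p, stored, step_um=0.5)
                assert abs(res.distance_um - oracle) < 0.6

    def test_vectorized_matches_scalar(self, rng):
        ring = star_ring(rng, np.zeros(2), 700.0)
        tr = LesionTracing([GAFocus(ring, "f")], "e")
        pts = rng.uniform(-1500, 1500, (10, 2))
        vec = signed_distances(pts, tr)
        for p, r in zip(pts, vec):
            assert r.distance_um == pytest.approx(signed_distance(p, tr).distance_um)


class TestZones:
    def test_junctional_equals_abs_distance_rule(self):
        zone = ZoneSpec.junctional()
        for d in np.linspace(-600, 600, 241):
            assert zone_membership(float(d), zone) == (abs(d) <= 250)

    @pytest.mark.parametrize("d,junctional,perilesional", [
        (-251.0, False, False),
        (-250.0, True, False),
        (-10.0, True, False),
        (0.0, True, True),
        (250.0, True, True),
        (251.0, False, True),
        (500.0, False, True),
        (501.0, False, False),
    ])
    def test_boundary_values(self, d, junctional, perilesional):
        assert zone_membership(d, ZoneSpec.junctional()) == junctional
        assert zone_membership(d, ZoneSpec.perilesional()) == perilesional

    def test_invalid_zone_bounds(self):
        with pytest.raises(Exception):
            ZoneSpec("junctional", 250.0, -250.0)


class TestSimulatedLesions:
    def test_roughness_zero_gives_circle_area(self, rng):
        config = SimulationConfig(n_eyes=1, lesion=LesionModel(
            n_foci_range=(1, 1), roughness=0.0, n_vertices=256))
        tracing = simulate_lesion(config, np.random.default_rng(3), "e")
        focus = tracing.foci[0]
        r = np.linalg.norm(focus.vertices_um - focus.vertices_um.mean(axis=0), axis=1)
        circle_area_mm2 = np.pi * np.mean(r) ** 2 / 1e6
        assert polygon_area(focus) == pytest.approx(circle_area_mm2, rel=0.01)

    def test_generated_polygons_always_valid_and_disjoint(self):
        config = SimulationConfig()
        for s in range(12):
            tr = simulate_lesion(config, np.random.default_rng(s), f"e{s}")
            for f in tr.foci:
                assert f.polygon.is_valid and polygon_area(f) > 0
            for i in range(len(tr.foci)):
                for j in range(i + 1, len(tr.foci)):
                    assert not tr.foci[i].polygon.intersects(tr.foci[j].polygon)

    def test_mean_focus_area_matches_configuration(self):
        config = SimulationConfig(lesion=LesionModel(n_foci_range=(1, 1)))
        rng = np.random.default_rng(11)
        areas = [polygon_area(simulate_lesion(config, rng, "e").foci[0])
                 for _ in range(1000)]
        assert np.mean(areas) == pytest.approx(config.lesion.mean_focus_area_mm2, rel=0.10)
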