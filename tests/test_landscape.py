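"""Zone construction, cover/length metrics and orientation decomposition."""

import math

import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import LineString, Point, box

from landgen.landscape import (
    AREA_CLASSES,
    LandscapeWindow,
    LandusePolygon,
    LinearElement,
    Zone,
    compute_link_metrics,
    compute_node_metrics,
    crop_weight,
    edge_density,
    green_settlement_fraction,
    make_buffer,
    make_strip,
    op_ratio,
    orientation_components,
    percent_cover,
    relative_length,
    shannon_diversity,
)
from landgen.synthetic import ScenarioConfig, generate_window


def full_zone(window):
    return Zone(window.extent, "buffer", 1.0, window.extent.centroid, window.extent.area / 1e4)


class TestZones:
    def test_buffer_area_near_disc(self, two_class_window):
        big = LandscapeWindow("B", box(0, 0, 1000, 1000), [], [])
        z = make_buffer(Point(500, 500), 125, big)
        assert z.area_ha * 1e4 == pytest.approx(math.pi * 125**2, rel=1e-3)

    def test_buffer_clipped_to_half_disc(self):
        big = LandscapeWindow("B", box(0, 0, 1000, 1000), [], [])
        z = make_buffer(Point(0, 500), 100, big)
        assert z.area_ha * 1e4 == pytest.approx(math.pi * 100**2 / 2, rel=1e-3)

    def test_buffer_contains_centre(self):
        big = LandscapeWindow("B", box(0, 0, 1000, 1000), [], [])
        z = make_buffer(Point(300, 300), 125, big)
        assert z.geometry.contains(Point(300, 300))

    def test_buffer_bad_distance(self, two_class_window):
        with pytest.raises(ValueError):
            make_buffer(Point(50, 50), 0, two_class_window)

    def test_strip_corners_and_area(self):
        big = LandscapeWindow("B", box(-100, -300, 1100, 300), [], [])
        z = make_strip(Point(0, 0), Point(1000, 0), "1:2", big)
        minx, miny, maxx, maxy = z.geometry.bounds
        assert (minx, miny, maxx, maxy) == pytest.approx((0, -250, 1000, 250))
        assert z.area_ha == pytest.approx(50.0)

    def test_strip_ratio_width(self):
        big = LandscapeWindow("B", box(-1000, -1000, 2000, 2000), [], [])
        z = make_strip(Point(0, 0), Point(900, 0), "2:3", big)
        miny, maxy = z.geometry.bounds[1], z.geometry.bounds[3]
        assert maxy - miny == pytest.approx(600.0)

    def test_strip_rotation_invariant_area(self):
        big = LandscapeWindow("B", box(-5000, -5000, 5000, 5000), [], [])
        z0 = make_strip(Point(0, 0), Point(1000, 0), "1:3", big)
        ang = math.radians(30)
        c2 = Point(1000 * math.cos(ang), 1000 * math.sin(ang))
        z1 = make_strip(Point(0, 0), c2, "1:3", big)
        assert z1.area_ha == pytest.approx(z0.area_ha, abs=1e-6)

    def test_coincident_centres_rejected(self, two_class_window):
        with pytest.raises(ValueError):
            make_strip(Point(10, 10), Point(10, 10), "1:2", two_class_window)


class TestCover:
    def test_half_cover(self, two_class_window):
        z = full_zone(two_class_window)
        assert percent_cover(z, two_class_window, "FOREST") == pytest.approx(50.0)

    def test_absent_class_zero(self, two_class_window):
        z = full_zone(two_class_window)
        assert percent_cover(z, two_class_window, "SETTLE") == 0.0

    def test_full_cover(self, two_class_window):
        z = Zone(box(0, 0, 40, 100), "buffer", 1.0, Point(20, 50), 0.4)
        assert percent_cover(z, two_class_window, "FOREST") == pytest.approx(100.0)

    def test_crop_weight_frequencies(self):
        p_all = LandusePolygon(box(0, 0, 1, 1), "ARABLE", crop_years={y: "RAPE" for y in range(2008, 2018)})
        assert crop_weight(p_all, "RAPE") == 1.0
        years = {y: ("MAIZE" if y < 2013 else "CEREAL") for y in range(2008, 2018)}
        p_half = LandusePolygon(box(0, 0, 1, 1), "ARABLE", crop_years=years)
        assert crop_weight(p_half, "MAIZE") == 0.5
        p_none = LandusePolygon(box(0, 0, 1, 1), "ARABLE")
        assert crop_weight(p_none, "RAPE") == 0.0

    def test_crop_cover_splits_arable(self, two_class_window):
        z = full_zone(two_class_window)
        rape = percent_cover(z, two_class_window, "RAPE")
        maize = percent_cover(z, two_class_window, "MAIZE")
        cereal = percent_cover(z, two_class_window, "CEREAL")
        arable = percent_cover(z, two_class_window, "ARABLE")
        assert rape == pytest.approx(25.0)
        assert maize == pytest.approx(25.0)
        assert rape + maize + cereal <= arable + 1e-9

    def test_cover_sum_is_100_on_tiling_map(self, two_class_window):
        z = Zone(
            box(10, 10, 90, 90), "buffer", 1.0, Point(50, 50), 0.64
        )
        total = sum(percent_cover(z, two_class_window, c) for c in AREA_CLASSES)
        assert total == pytest.approx(100.0, abs=1e-6)


class TestIndices:
    def test_shannon_single_class(self):
        w = LandscapeWindow("S", box(0, 0, 10, 10), [LandusePolygon(box(0, 0, 10, 10), "GRASS")], [])
        assert shannon_diversity(full_zone(w), w) == 0.0

    def test_shannon_two_equal(self, two_class_window):
        assert shannon_diversity(full_zone(two_class_window), two_class_window) == pytest.approx(math.log(2))

    def test_shannon_four_equal(self):
        polys = [
            LandusePolygon(box(0, 0, 50, 50), "FOREST"),
            LandusePolygon(box(50, 0, 100, 50), "GRASS"),
            LandusePolygon(box(0, 50, 50, 100), "ARABLE"),
            LandusePolygon(box(50, 50, 100, 100), "SETTLE"),
        ]
        w = LandscapeWindow("S", box(0, 0, 100, 100), polys, [])
        assert shannon_diversity(full_zone(w), w) == pytest.approx(math.log(4))

    def test_edge_density_uniform_zero(self):
        w = LandscapeWindow("E", box(0, 0, 100, 100), [LandusePolygon(box(0, 0, 100, 100), "GRASS")], [])
        assert edge_density(full_zone(w), w) == 0.0

    def test_edge_density_two_parcels(self, two_class_window):
        # one 100 m internal boundary in a 1 ha zone
        assert edge_density(full_zone(two_class_window), two_class_window) == pytest.approx(100.0)

    def test_edge_density_checkerboard(self, checkerboard_window):
        # internal between-class edges: two 100 m crossings = 200 m in 1 ha
        assert edge_density(full_zone(checkerboard_window), checkerboard_window) == pytest.approx(200.0)

    def test_propgreen_weighted(self):
        polys = [
            LandusePolygon(box(0, 0, 50, 100), "SETTLE", green_fraction=0.2),
            LandusePolygon(box(50, 0, 100, 100), "SETTLE", green_fraction=0.6),
        ]
        w = LandscapeWindow("G", box(0, 0, 100, 100), polys, [])
        assert green_settlement_fraction(full_zone(w), w) == pytest.approx(0.4)

    def test_propgreen_no_settlement(self, two_class_window):
        assert green_settlement_fraction(full_zone(two_class_window), two_class_window) == 0.0


class TestLines:
    def test_relative_length_inside(self):
        w = LandscapeWindow(
            "L", box(0, 0, 100, 100), [], [LinearElement(LineString([(0, 50), (100, 50)]), "LROAD")]
        )
        assert relative_length(full_zone(w), w, "LROAD") == pytest.approx(100.0)

    def test_relative_length_outside(self):
        w = LandscapeWindow(
            "L", box(0, 0, 100, 100), [], [LinearElement(LineString([(0, 50), (100, 50)]), "LROAD")]
        )
        z = Zone(box(0, 60, 100, 100), "buffer", 1.0, Point(50, 80), 0.4)
        assert relative_length(z, w, "LROAD") == 0.0

    def test_relative_length_half_clipped(self):
        w = LandscapeWindow(
            "L", box(0, 0, 100, 100), [], [LinearElement(LineString([(0, 50), (100, 50)]), "LROAD")]
        )
        z = Zone(box(0, 0, 50, 100), "buffer", 1.0, Point(25, 50), 0.5)
        assert relative_length(z, w, "LROAD") == pytest.approx(50.0 / 0.5)


class TestOrientation:
    def make_strip_zone(self):
        big = LandscapeWindow("O", box(-100, -400, 1100, 400), [], [])
        return big, make_strip(Point(0, 0), Point(1000, 0), "2:3", big)

    def test_parallel_segment(self):
        big, z = self.make_strip_zone()
        big.lines.append(LinearElement(LineString([(100, 10), (400, 10)]), "LWOOD"))
        par, orth = orientation_components(z, big, "LWOOD")
        assert par == pytest.approx(300.0)
        assert orth == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_segment(self):
        big, z = self.make_strip_zone()
        l = 100 / math.sqrt(2)
        big.lines.append(LinearElement(LineString([(500, 0), (500 + l, l)]), "LWOOD"))
        par, orth = orientation_components(z, big, "LWOOD")
        assert par == pytest.approx(100 / math.sqrt(2), rel=1e-9)
        assert orth == pytest.approx(100 / math.sqrt(2), rel=1e-9)

    def test_buffer_perpendicular_feature(self):
        w = LandscapeWindow("O", box(0, 0, 1000, 1000), [], [])
        # segment whose midpoint->centre direction is perpendicular to it
        w.lines.append(LinearElement(LineString([(400, 700), (600, 700)]), "LWATER"))
        z = make_buffer(Point(500, 500), 400, w)
        par, orth = orientation_components(z, w, "LWATER")
        assert par == pytest.approx(0.0, abs=1e-9)
        assert orth == pytest.approx(200.0)

    def test_radial_feature_is_parallel(self):
        w = LandscapeWindow("O", box(0, 0, 1000, 1000), [], [])
        w.lines.append(LinearElement(LineString([(500, 600), (500, 800)]), "LWATER"))
        z = make_buffer(Point(500, 500), 400, w)
        par, orth = orientation_components(z, w, "LWATER")
        assert par == pytest.approx(200.0)
        assert orth == pytest.approx(0.0, abs=1e-9)

    def test_pythagoras_per_segment(self):
        rng = np.random.default_rng(0)
        big, z = self.make_strip_zone()
        for _ in range(100):
            p0 = rng.uniform([100, -200], [900, 200])
            ang = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(10, 100)
            p1 = p0 + length * np.array([math.cos(ang), math.sin(ang)])
            seg = LineString([tuple(p0), tuple(p1)])
            if not z.geometry.covers(seg):
                continue
            w2 = LandscapeWindow("O", big.extent, [], [LinearElement(seg, "LWOOD")])
            par, orth = orientation_components(z, w2, "LWOOD")
            assert par**2 + orth**2 == pytest.approx(length**2, rel=1e-9)

    def test_random_polylines_match_segment_oracle(self):
        """1000 random polylines, strip and buffer mode, against a brute
        per-segment projection written independently of the implementation."""
        rng = np.random.default_rng(1)
        big = LandscapeWindow("O", box(0, 0, 2000, 2000), [], [])
        strip = make_strip(Point(200, 1000), Point(1800, 1000), "1:3", big)
        buffer_zone = make_buffer(Point(1000, 1000), 600, big)
        for kind, zone in (("strip", strip), ("buffer", buffer_zone)):
            for _ in range(500):
                n_pts = rng.integers(2, 6)
                pts = rng.uniform(0, 2000, (n_pts, 2))
                line = LineString(pts)
                w2 = LandscapeWindow("O", big.extent, [], [LinearElement(line, "LROAD")])
                par, orth = orientation_components(zone, w2, "LROAD")
                # oracle
                exp_par = exp_orth = 0.0
                clipped = line.intersection(zone.geometry)
                pieces = (
                    [clipped]
                    if clipped.geom_type == "LineString"
                    else [g for g in getattr(clipped, "geoms", []) if g.geom_type == "LineString"]
                )
                for piece in pieces:
                    if piece.length == 0:
                        continue
                    if kind == "strip":
                        u = np.array([1.0, 0.0])
                    else:
                        mid = piece.interpolate(0.5, normalized=True)
                        v = np.array([1000.0 - mid.x, 1000.0 - mid.y])
                        u = v / np.linalg.norm(v)
                    cs = np.asarray(piece.coords)
                    for a, b in zip(cs[:-1], cs[1:]):
                        d = b - a
                        seg_len = math.hypot(*d)
                        if seg_len == 0:
                            continue
                        cos_t = abs(float(d @ u)) / seg_len
                        exp_par += seg_len * cos_t
                        exp_orth += seg_len * math.sqrt(max(0.0, 1 - cos_t**2))
                assert par == pytest.approx(exp_par, abs=1e-9)
                assert orth == pytest.approx(exp_orth, abs=1e-9)

    @pytest.mark.parametrize(
        "par,orth,expected",
        [(5.0, 5.0, 1.0), (999.0, 0.0, 0.001), (0.0, 99.0, 100.0)],
    )
    def test_op_ratio(self, par, orth, expected):
        assert op_ratio(par, orth) == pytest.approx(expected)

    def test_op_ratio_rejects_negative(self):
        with pytest.raises(ValueError):
            op_ratio(-1.0, 2.0)


class TestAssembly:
    def test_node_metric_columns(self, two_class_window):
        df = compute_node_metrics(two_class_window, {"P0": Point(50, 50)}, scales=(30.0, 45.0))
        per_scale = 8 + 3 + 4 * 2 + 3  # classes + crops + lines&O:P + SHANNON/EDGEDEN/PROPGREEN
        assert df.shape == (1, per_scale * 2)
        assert "FOREST_30" in df.columns and "OP_LROAD_45" in df.columns

    def test_hand_computed_covers(self, two_class_window):
        df = compute_node_metrics(two_class_window, {"P0": Point(50, 50)}, scales=(40.0,))
        # buffer at the class boundary: half forest, half arable
        assert df.loc["P0", "FOREST_40"] == pytest.approx(50.0, abs=0.1)
        assert df.loc["P0", "ARABLE_40"] == pytest.approx(50.0, abs=0.1)
        assert df.loc["P0", "RAPE_40"] == pytest.approx(25.0, abs=0.1)

    def test_link_table_index(self, two_class_window):
        pairs = {("a", "b"): (Point(20, 50), Point(80, 50))}
        df = compute_link_metrics(two_class_window, pairs, ratios=("1:2",))
        assert df.index.tolist() == [("a", "b")]
        assert "SHANNON_1:2" in df.columns

    def test_degenerate_strip_approximates_buffer(self, two_class_window):
        """A fat 2:3 strip around nearly coincident centres behaves like a
        small buffer at the shared location."""
        c = Point(50, 50)
        strip = make_strip(Point(49, 50), Point(51, 50), "2:3", two_class_window)
        # compare to a small buffer's covers
        buf = make_buffer(c, 1.0, two_class_window)
        for cls in ("FOREST", "ARABLE"):
            a = percent_cover(strip, two_class_window, cls)
            b = percent_cover(buf, two_class_window, cls)
            assert a == pytest.approx(b, abs=5.0)


class TestRigidMotionInvariance:
    def test_metrics_invariant_under_rotation_translation(self):
        cfg = ScenarioConfig(seed=9, n_parcels=25, window_size_m=2000.0)
        w = generate_window(cfg, 0)
        centre = Point(1000, 1000)
        z = make_buffer(centre, 400, w)
        base = {
            "FOREST": percent_cover(z, w, "FOREST"),
            "SHANNON": shannon_diversity(z, w),
            "EDGEDEN": edge_density(z, w),
            "LROAD": relative_length(z, w, "LROAD"),
            "OC": orientation_components(z, w, "LROAD"),
        }
        ang, dx, dy = 37.0, 500.0, -250.0

        def move(g):
            return affinity.translate(affinity.rotate(g, ang, origin=(0, 0)), dx, dy)

        w2 = LandscapeWindow(
            "R",
            move(w.extent),
            [
                type(p)(move(p.geometry), p.landuse, p.green_fraction, p.crop_years)
                for p in w.polygons
            ],
            [type(l)(move(l.geometry), l.line_class) for l in w.lines],
        )
        c2 = move(centre)
        # transform the zone polygon itself so the disc discretization is
        # identical on both sides of the comparison
        z2 = Zone(move(z.geometry), "buffer", 400.0, c2, z.area_ha)
        assert percent_cover(z2, w2, "FOREST") == pytest.approx(base["FOREST"], rel=1e-6)
        assert shannon_diversity(z2, w2) == pytest.approx(base["SHANNON"], rel=1e-6)
        assert edge_density(z2, w2) == pytest.approx(base["EDGEDEN"], rel=1e-6)
        assert relative_length(z2, w2, "LROAD") == pytest.approx(base["LROAD"], rel=1e-6)
        p2, o2 = orientation_components(z2, w2, "LROAD")
        assert p2 == pytest.approx(base["OC"][0], rel=1e-6)
        assert o2 == pytest.approx(base["OC"][1], rel=1e-6)

    def test_buffer_monotone_in_radius(self):
        cfg = ScenarioConfig(seed=10, n_parcels=25, window_size_m=2000.0)
        w = generate_window(cfg, 0)
        prev = -1.0
        for r in (100, 200, 400, 800):
            z = make_buffer(Point(1000, 1000), r, w)
            area = percent_cover(z, w, "ARABLE") / 100.0 * z.area_ha
            assert area >= prev - 1e-9
            prev = area
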