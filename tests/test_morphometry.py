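"""Vertebral height-ratio measurement: frames, points, heights, ratios."""

import numpy as np
import pytest

from vertmorph import (
    Plane,
    TriMesh,
    VertebraSpec,
    analytic_vhr,
    build_frame,
    compute_vhr,
    curve_vhr_summary,
    generate_vertebra_mesh,
    measure_heights,
    measure_vertebra,
    measurement_points,
)
from vertmorph.morphometry import (
    HeightSet,
    MeasurementError,
    MeasurementFrame,
    MeasurementPoints,
    VertebralBodyModel,
    VHRResult,
)

from conftest import random_rotation


def canonical_frame(G=(0.0, 0.0, 0.0)):
    return MeasurementFrame(
        G=np.asarray(G, dtype=float),
        vertical_axis=np.array([0.0, 0.0, 1.0]),
        sagittal_plane=Plane(np.array([1.0, 0.0, 0.0]), float(G[0])),
        anterior_dir=np.array([0.0, 1.0, 0.0]),
    )


def rim_polygon(r_x, r_y, n=2000, z=0.0):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([r_x * np.cos(th), r_y * np.sin(th), np.full(n, z)])


def transformed_model(model, rotation=None, translation=None, scale=None):
    def tp(p):
        q = np.asarray(p, dtype=float)
        if scale is not None:
            q = q * scale
        if rotation is not None:
            q = rotation @ q
        if translation is not None:
            q = q + translation
        return q

    return VertebralBodyModel(
        mesh=model.mesh.transformed(rotation, translation, scale),
        landmark_a=tp(model.landmark_a),
        landmark_b=tp(model.landmark_b),
        level=model.level,
        concave_side=model.concave_side,
    )


def mirrored_model(model, swap_side: bool):
    """Reflection across the canonical sagittal plane (x -> -x)."""
    verts = model.mesh.vertices.copy()
    verts[:, 0] *= -1
    mesh = TriMesh(verts, model.mesh.faces[:, ::-1].copy(),
                   None if model.mesh.region is None else model.mesh.region.copy())
    side = model.concave_side
    if swap_side:
        side = "right" if side == "left" else "left"
    a, b = model.landmark_a.copy(), model.landmark_b.copy()
    a[0] *= -1
    b[0] *= -1
    return VertebralBodyModel(mesh=mesh, landmark_a=a, landmark_b=b,
                              level=model.level, concave_side=side)


class TestBuildFrame:
    def test_symmetric_construction(self):
        # body of height 25 whose lower endplate sits at z = -2
        spec = VertebraSpec(r_x=25.0, r_y=22.0, height=25.0, tilt_deg=0.0)
        model = transformed_model(
            generate_vertebra_mesh(spec), translation=np.array([0.0, 0.0, -2.0])
        )
        assert np.allclose(model.landmark_a, [0, -22, 23], atol=1e-9)
        assert np.allclose(model.landmark_b, [0, -22, -2], atol=1e-9)
        frame = build_frame(model)
        assert np.allclose(frame.G, [0, 0, 10.5], atol=1e-6)
        assert np.allclose(frame.vertical_axis, [0, 0, 1], atol=1e-9)
        assert np.allclose(np.abs(frame.sagittal_plane.normal), [1, 0, 0], atol=1e-6)
        assert abs(frame.sagittal_plane.signed_distance(frame.G)) < 1e-9
        assert np.allclose(frame.anterior_dir, [0, 1, 0], atol=1e-6)
        assert abs(frame.anterior_dir @ frame.vertical_axis) < 1e-12

    def test_rigid_equivariance(self, rng, symmetric_model):
        frame0 = build_frame(symmetric_model)
        R, t = random_rotation(rng), rng.normal(scale=40, size=3)
        frame1 = build_frame(transformed_model(symmetric_model, R, t))
        assert np.allclose(frame1.G, R @ frame0.G + t, atol=1e-6)
        assert np.allclose(frame1.vertical_axis, R @ frame0.vertical_axis, atol=1e-6)
        assert np.allclose(np.abs(frame1.sagittal_plane.normal @ (R @ frame0.sagittal_plane.normal)), 1.0, atol=1e-6)
        assert np.allclose(frame1.anterior_dir, R @ frame0.anterior_dir, atol=1e-6)

    def test_degenerate_landmarks_rejected(self, symmetric_model):
        with pytest.raises(ValueError, match="distinct"):
            VertebralBodyModel(
                mesh=symmetric_model.mesh,
                landmark_a=np.zeros(3),
                landmark_b=np.zeros(3),
            )


class TestMeasurementPoints:
    def test_circular_rim_closed_form(self):
        pts = measurement_points(canonical_frame(), rim_polygon(20.0, 20.0))
        s = 20.0 / np.sqrt(2.0)
        assert np.allclose(sorted(pts[("anterior", s_)][0] for s_ in ("left", "right")),
                           sorted([-s, s]), atol=1e-3)
        for side in ("left", "right"):
            assert pts[("anterior", side)][1] == pytest.approx(s, abs=1e-3)
            assert pts[("posterior", side)][1] == pytest.approx(-s, abs=1e-3)
            assert abs(pts[("middle", side)][1]) < 1e-3
            assert abs(abs(pts[("middle", side)][0]) - 20.0) < 1e-3
        # left/right sit on opposite sides of the sagittal plane
        assert pts[("middle", "left")][0] * pts[("middle", "right")][0] < 0

    def test_elliptical_rim_matches_conic_oracle(self):
        r_x, r_y = 25.0, 18.0
        pts = measurement_points(canonical_frame(), rim_polygon(r_x, r_y))
        # each rotated plane contains the in-plane direction (sin a, cos a, 0);
        # its ellipse crossings are +/- s(a) * that direction
        u45 = np.array([np.sin(np.deg2rad(45.0)), np.cos(np.deg2rad(45.0)), 0.0])
        s45 = 1.0 / np.sqrt((u45[0] / r_x) ** 2 + (u45[1] / r_y) ** 2)
        x_a, y_a = s45 * u45[0], s45 * u45[1]
        expected = {
            ("anterior", "left"): (-x_a, y_a), ("anterior", "right"): (x_a, y_a),
            ("posterior", "left"): (-x_a, -y_a), ("posterior", "right"): (x_a, -y_a),
            ("middle", "left"): (-r_x, 0.0), ("middle", "right"): (r_x, 0.0),
        }
        for key, (ex, ey) in expected.items():
            assert pts[key][0] == pytest.approx(ex, abs=1e-2)
            assert pts[key][1] == pytest.approx(ey, abs=1e-2)
            assert abs(pts[key][2]) < 1e-9

    def test_rotates_with_the_frame(self, rng):
        rim = rim_polygon(22.0, 16.0)
        pts0 = measurement_points(canonical_frame(), rim)
        R = random_rotation(rng)
        t = rng.normal(scale=25, size=3)
        frame1 = MeasurementFrame(
            G=R @ np.zeros(3) + t,
            vertical_axis=R @ np.array([0.0, 0, 1]),
            sagittal_plane=Plane.from_point_normal(t, R @ np.array([1.0, 0, 0])),
            anterior_dir=R @ np.array([0.0, 1, 0]),
        )
        pts1 = measurement_points(frame1, rim @ R.T + t)
        for key, p in pts0.items():
            assert np.allclose(pts1[key], R @ p + t, atol=1e-6)

    def test_wrong_crossing_count_reports_plane_angle(self):
        tiny = rim_polygon(1.0, 1.0, n=16, z=0.0) + np.array([100.0, 0, 0])
        with pytest.raises(MeasurementError, match=r"deg crossed the rim 0 times"):
            measurement_points(canonical_frame(), tiny)


class TestMeasureHeights:
    @staticmethod
    def _points():
        s = 20.0 / np.sqrt(2.0)
        return MeasurementPoints({
            ("anterior", "left"): np.array([-s, s, 0.0]),
            ("anterior", "right"): np.array([s, s, 0.0]),
            ("middle", "left"): np.array([-20.0, 0.0, 0.0]),
            ("middle", "right"): np.array([20.0, 0.0, 0.0]),
            ("posterior", "left"): np.array([-s, -s, 0.0]),
            ("posterior", "right"): np.array([s, -s, 0.0]),
        })

    def test_parallel_endplates(self):
        plane = Plane(np.array([0.0, 0, 1.0]), 25.0)
        hs = measure_heights(self._points(), plane, np.array([0.0, 0, 12.5]))
        for key in hs.heights:
            assert hs[key] == pytest.approx(25.0, abs=1e-6)

    def test_tilted_plane_closed_form(self):
        phi = np.deg2rad(3.0)
        H, r = 25.0, 20.0
        normal = np.array([-np.sin(phi), 0.0, np.cos(phi)])
        plane = Plane(normal, float(normal @ np.array([0, 0, H])))
        hs = measure_heights(self._points(), plane, np.array([0.0, 0, H / 2]))
        assert hs[("middle", "left")] == pytest.approx((H - r * np.tan(phi)) * np.cos(phi), abs=1e-6)
        assert hs[("middle", "right")] == pytest.approx((H + r * np.tan(phi)) * np.cos(phi), abs=1e-6)
        s = r / np.sqrt(2.0)
        assert hs[("anterior", "left")] == pytest.approx((H - s * np.tan(phi)) * np.cos(phi), abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        plane0 = Plane(np.array([0.0, 0, 1.0]), 25.0)
        hs0 = measure_heights(self._points(), plane0, np.array([0.0, 0, 12.5]))
        R, t = random_rotation(rng), rng.normal(scale=30, size=3)
        moved = MeasurementPoints({k: R @ p + t for k, p in self._points().items()})
        normal1 = R @ plane0.normal
        plane1 = Plane.from_point_normal(R @ np.array([0, 0, 25.0]) + t, normal1)
        hs1 = measure_heights(moved, plane1, R @ np.array([0.0, 0, 12.5]) + t)
        for key in hs0.heights:
            assert hs1[key] == pytest.approx(hs0[key], abs=1e-9)

    def test_inverted_geometry_rejected(self):
        plane = Plane(np.array([0.0, 0, 1.0]), 25.0)
        with pytest.raises(MeasurementError, match="far side"):
            measure_heights(self._points(), plane, np.array([0.0, 0, 40.0]))


class TestComputeVhr:
    def test_simple_arithmetic(self):
        hs = HeightSet({(p, s): 19.0 if s == "left" else 20.0
                        for p in ("anterior", "middle", "posterior")
                        for s in ("left", "right")})
        res = compute_vhr(hs, "left")
        assert res.rounded() == (0.950, 0.950, 0.950)

    def test_equal_heights_give_exactly_one(self):
        hs = HeightSet({(p, s): 22.0 for p in ("anterior", "middle", "posterior")
                        for s in ("left", "right")})
        assert np.all(compute_vhr(hs, "right").triplet == 1.0)

    def test_nonpositive_height_rejected(self):
        hs = HeightSet({(p, s): 0.0 if (p, s) == ("middle", "right") else 20.0
                        for p in ("anterior", "middle", "posterior")
                        for s in ("left", "right")})
        with pytest.raises(ValueError, match="non-positive"):
            compute_vhr(hs, "left")


class TestMeasureVertebra:
    def test_mirror_symmetric_body_gives_unit_ratios(self, symmetric_model):
        assert np.allclose(measure_vertebra(symmetric_model).triplet, 1.0, atol=0.01)

    def test_wedged_body_matches_analytic_oracle(self, wedged_spec):
        measured = measure_vertebra(generate_vertebra_mesh(wedged_spec)).triplet
        expected = analytic_vhr(wedged_spec)
        assert np.abs(measured - expected).max() < 0.005
        # the explicit closed form for the circular middle pair
        mid = (25.0 - 20.0 * np.tan(np.deg2rad(3.0))) / (25.0 + 20.0 * np.tan(np.deg2rad(3.0)))
        assert measured[1] == pytest.approx(mid, abs=0.005)

    def test_rigid_motion_invariance(self, rng, wedged_spec):
        model = generate_vertebra_mesh(wedged_spec)
        base = measure_vertebra(model).triplet
        R, t = random_rotation(rng), rng.normal(scale=50, size=3)
        moved = measure_vertebra(transformed_model(model, R, t)).triplet
        assert np.abs(base - moved).max() < 1e-6

    def test_scale_invariance(self, wedged_spec):
        model = generate_vertebra_mesh(wedged_spec)
        base = measure_vertebra(model).triplet
        scaled = measure_vertebra(transformed_model(model, scale=2.7)).triplet
        assert np.abs(base - scaled).max() < 1e-9

    def test_mirror_antisymmetry(self, wedged_spec):
        model = generate_vertebra_mesh(wedged_spec)
        base = measure_vertebra(model).triplet
        swapped = measure_vertebra(mirrored_model(model, swap_side=True)).triplet
        assert np.abs(base - swapped).max() < 1e-6
        unswapped = measure_vertebra(mirrored_model(model, swap_side=False)).triplet
        assert np.abs(unswapped - 1.0 / base).max() < 1e-6

    def test_vhr_strictly_decreases_with_tilt(self):
        prev = np.array([np.inf] * 3)
        for phi in (1.0, 2.5, 4.0, 6.0, 9.0):
            spec = VertebraSpec(tilt_deg=phi)
            trip = measure_vertebra(generate_vertebra_mesh(spec)).triplet
            assert np.all(trip < prev)
            prev = trip


class TestCurveSummary:
    def test_single_result(self):
        df = curve_vhr_summary([VHRResult(0.9, 0.8, 0.95)])
        assert np.allclose(df["mean"], [0.9, 0.8, 0.95])
        assert np.all(df["sd"] == 0.0)

    def test_two_results(self):
        df = curve_vhr_summary([VHRResult(0.9, 0.9, 0.9), VHRResult(1.0, 1.0, 1.0)])
        assert np.allclose(df["mean"], 0.95)
        assert np.allclose(df["sd"], 0.0707, atol=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            curve_vhr_summary([])
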