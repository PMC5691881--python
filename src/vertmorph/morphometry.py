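"""Coronal wedge morphometry of vertebral bodies.

The measurement quantifies coronal-plane wedging of a single vertebral body
from its 3D surface mesh.  An intrinsic anatomical frame is built from the
solid's center of gravity G and two midline landmarks a (upper endplate) and
b (lower endplate): the vertical axis is the unit vector from b to a, and the
sagittal plane contains G, a and b.  The sagittal plane is then rotated about
the vertical axis by +45°, -45° and +90°; each rotated plane crosses the
lower-endplate rim twice, giving six measurement points — an anterior, a
middle (coronal) and a posterior left/right pair.  Each height is the
perpendicular distance from a measurement point to the total-least-squares
plane fitted to the upper endplate.  The vertebral height ratio (VHR) at each
anteroposterior position is the concave-side height divided by the
convex-side height; parallel endplates give VHR = 1, and coronal wedging that
shortens the concave side gives VHR < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    Plane,
    TriMesh,
    extract_endplate,
    fit_plane_tls,
    plane_rim_intersections,
    rotate_plane,
    unit,
    volume_centroid,
)

__all__ = [
    "VertebralBodyModel",
    "MeasurementFrame",
    "MeasurementPoints",
    "HeightSet",
    "VHRResult",
    "MeasurementError",
    "build_frame",
    "measurement_points",
    "measure_heights",
    "compute_vhr",
    "measure_vertebra",
    "curve_vhr_summary",
]

PARTS = ("anterior", "middle", "posterior")
SIDES = ("left", "right")


class MeasurementError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class VertebralBodyModel:
    """Vertebral body mesh (posterior elements removed) plus its landmarks.

    ``landmark_a``/``landmark_b`` are the anterior edges of the vertebral
    foramen on the upper and lower endplates; ``concave_side`` is the curve's
    laterality seen from the radiograph (an input — a single vertebra cannot
    know it).
    """

    mesh: TriMesh
    landmark_a: np.ndarray
    landmark_b: np.ndarray
    level: str = ""
    concave_side: str = "left"
    patient_id: str = ""
    curve_id: str = ""

    def __post_init__(self):
        self.landmark_a = np.asarray(self.landmark_a, dtype=float)
        self.landmark_b = np.asarray(self.landmark_b, dtype=float)
        if self.landmark_a.shape != (3,) or self.landmark_b.shape != (3,):
            raise ValueError("landmarks must be 3-vectors")
        if np.allclose(self.landmark_a, self.landmark_b):
            raise ValueError("landmarks a and b must be distinct")
        if self.concave_side not in SIDES:
            raise ValueError("concave_side must be 'left' or 'right'")


@dataclass
class MeasurementFrame:
    """Intrinsic frame of one vertebra: G, vertical axis, sagittal plane."""

    G: np.ndarray
    vertical_axis: np.ndarray
    sagittal_plane: Plane
    anterior_dir: np.ndarray

    @property
    def left_dir(self) -> np.ndarray:
        return np.cross(self.vertical_axis, self.anterior_dir)


@dataclass
class MeasurementPoints:
    """Six labeled points on the lower-endplate rim."""

    points: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.points[key]

    def items(self):
        return self.points.items()


@dataclass
class HeightSet:
    """Six vertebral heights (mm), keyed (part, side)."""

    heights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.heights[key]


@dataclass
class VHRResult:
    """Concave/convex vertebral height ratios with provenance."""

    vhr_anterior: float
    vhr_middle: float
    vhr_posterior: float
    level: str = ""
    patient_id: str = ""
    curve_id: str = ""

    @property
    def triplet(self) -> np.ndarray:
        return np.array([self.vhr_anterior, self.vhr_middle, self.vhr_posterior])

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        """Display precision used in reports; values stay unrounded internally."""
        return tuple(round(v, ndigits) for v in self.triplet)


def build_frame(model: VertebralBodyModel) -> MeasurementFrame:
    """Center of gravity, vertical axis (caudal to cranial), sagittal plane
    and in-endplate anterior direction of one vertebral body."""
    G = volume_centroid(model.mesh)
    a, b = model.landmark_a, model.landmark_b
    axis = unit(a - b, "vertical axis")
    g_vec = G - a
    n = np.cross(axis, g_vec)
    if np.linalg.norm(n) < 1e-9 * max(1.0, np.linalg.norm(g_vec)):
        raise ValueError(
            "degenerate sagittal plane: center of gravity is collinear with "
            "the foramen landmarks"
        )
    normal = unit(n)
    sagittal = Plane(normal, float(normal @ G))
    w = G - 0.5 * (a + b)
    w = w - (w @ axis) * axis
    anterior = unit(w, "anterior direction")
    return MeasurementFrame(G, axis, sagittal, anterior)


def measurement_points(frame: MeasurementFrame, lower_rim) -> MeasurementPoints:
    """Place the six measurement points on the lower-endplate rim.

    The sagittal plane is rotated about the vertical axis by +45°, -45° and
    +90°; the coronal (+90°) crossings are the middle pair, and each 45° plane
    contributes one anterior and one posterior point (sign of the
    anterior-direction component).  Left/right follows the sign against
    ``vertical_axis x anterior_dir``.
    """
    crossings: dict[float, np.ndarray] = {}
    for angle in (90.0, 45.0, -45.0):
        plane = rotate_plane(frame.sagittal_plane, frame.G, frame.vertical_axis, angle)
        pts = plane_rim_intersections(plane, lower_rim)
        if len(pts) != 2:
            raise MeasurementError(
                "points",
                f"rotated plane at {angle:+g} deg crossed the rim "
                f"{len(pts)} times (expected 2)",
            )
        crossings[angle] = pts

    def side_of(p) -> str:
        s = float((p - frame.G) @ frame.left_dir)
        return "left" if s > 0 else "right"

    out: dict[tuple[str, str], np.ndarray] = {}
    mid = crossings[90.0]
    if side_of(mid[0]) == side_of(mid[1]):
        raise MeasurementError("points", "middle pair fell on one side of the sagittal plane")
    for p in mid:
        out[("middle", side_of(p))] = p

    ant_pts, post_pts = [], []
    for angle in (45.0, -45.0):
        pair = crossings[angle]
        comp = [(float((p - frame.G) @ frame.anterior_dir), p) for p in pair]
        comp.sort(key=lambda cp: cp[0])
        if comp[0][0] >= 0 or comp[1][0] <= 0:
            raise MeasurementError(
                "points",
                f"plane at {angle:+g} deg did not yield one anterior and one "
                "posterior rim point",
            )
        post_pts.append(comp[0][1])
        ant_pts.append(comp[1][1])
    for part, pts in (("anterior", ant_pts), ("posterior", post_pts)):
        sides = [side_of(p) for p in pts]
        if sides[0] == sides[1]:
            raise MeasurementError("points", f"{part} pair fell on one side of the sagittal plane")
        for s, p in zip(sides, pts):
            out[(part, s)] = p
    return MeasurementPoints(out)


def measure_heights(
    points: MeasurementPoints, upper_plane: Plane, interior_point
) -> HeightSet:
    """Perpendicular distances from the measurement points to the fitted
    upper-endplate plane.  All points must lie on the same side of the plane
    as the body interior; a point on the far side means inverted geometry."""
    s_int = float(upper_plane.signed_distance(np.asarray(interior_point, dtype=float)))
    heights: dict[tuple[str, str], float] = {}
    for key, p in points.items():
        s = float(upper_plane.signed_distance(p))
        if s * s_int <= 0:
            raise MeasurementError(
                "heights",
                f"measurement point {key} lies on the far side of the upper "
                "endplate plane (inverted geometry)",
            )
        heights[key] = abs(s)
    return HeightSet(heights)


def compute_vhr(
    heights: HeightSet,
    concave_side: str,
    level: str = "",
    patient_id: str = "",
    curve_id: str = "",
) -> VHRResult:
    """Concave-height / convex-height ratio at each anteroposterior part."""
    if concave_side not in SIDES:
        raise ValueError("concave_side must be 'left' or 'right'")
    convex_side = "right" if concave_side == "left" else "left"
    ratios = {}
    for part in PARTS:
        d = heights[(part, concave_side)]
        D = heights[(part, convex_side)]
        if D <= 0 or d <= 0:
            raise ValueError(f"non-positive vertebral height at {part}")
        ratios[part] = d / D
    return VHRResult(
        ratios["anterior"], ratios["middle"], ratios["posterior"],
        level=level, patient_id=patient_id, curve_id=curve_id,
    )


def measure_vertebra(model: VertebralBodyModel) -> VHRResult:
    """Full single-vertebra pipeline: frame, endplates, plane fit, points,
    heights, ratios.  Errors propagate tagged with the failing stage."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except MeasurementError:
            raise
        except Exception as exc:
            raise MeasurementError(name, str(exc)) from exc

    frame = stage("frame", build_frame, model)
    upper_ids, _ = stage(
        "endplates", extract_endplate, model.mesh, "upper", frame.vertical_axis
    )
    _, lower_rim = stage(
        "endplates", extract_endplate, model.mesh, "lower", frame.vertical_axis
    )
    upper_plane = stage("plane_fit", fit_plane_tls, model.mesh.vertices[upper_ids])
    points = measurement_points(frame, lower_rim)
    heights = measure_heights(points, upper_plane, frame.G)
    return stage(
        "vhr",
        compute_vhr,
        heights,
        model.concave_side,
        model.level,
        model.patient_id,
        model.curve_id,
    )


def curve_vhr_summary(results) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator; 0 for a single value) of the VHR
    at each part over a set of vertebra results."""
    results = list(results)
    if not results:
        raise ValueError("no VHR results to summarize")
    arr = np.array([r.triplet for r in results], dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    return pd.DataFrame({"mean": mean, "sd": sd, "n": len(arr)}, index=list(PARTS))
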