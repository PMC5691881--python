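"""Synthetic vertebrae, CT phantoms and whole study cohorts.

Everything downstream of segmentation is testable without patient data:

* :func:`generate_vertebra_mesh` builds a watertight, region-labeled
  vertebral-body mesh — an elliptical lower endplate, an upper endplate
  rigidly wedged by a coronal tilt ``phi`` about the anteroposterior axis
  (concave side lower), and a waisted lateral wall — with midline landmarks
  standing in for the anterior edges of the vertebral foramen.
* :func:`analytic_vhr` gives the closed-form height ratios of that geometry:
  at lateral offset ``x`` from the axis the heights are ``(H -+ x tan(phi)) *
  cos(phi)`` on the concave/convex side, so ``VHR(x) = (H - x tan(phi)) /
  (H + x tan(phi))`` with ``x = r_x`` at the middle and ``x = r_x r_y /
  sqrt(r_x^2 + r_y^2)`` at the 45-degree (anterior/posterior) crossings of
  the ellipse.
* :func:`generate_ct_phantom` builds an ellipsoidal body with a cortical
  shell and Gaussian trabecular HU for the spherical-ROI densitometry.
* :func:`generate_cohort` realizes full neuromuscular (NS) and idiopathic
  (IS) scoliosis groups: per-vertebra true VHR triplets drawn from the group
  distributions, a tilt solved to realize the drawn middle ratio, Cobb
  erect/bending pairs, per-vertebra HU draws, and per-patient substreams of a
  master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .geometry import REGION_LOWER, REGION_UPPER, REGION_WALL, TriMesh
from .morphometry import VertebralBodyModel, measure_vertebra
from .radiographic import LEVELS, flexibility_index, level_order

__all__ = [
    "VertebraSpec",
    "PhantomSpec",
    "CurveParams",
    "CohortSpec",
    "VertebraRecord",
    "CurveRecord",
    "PatientRecord",
    "Cohort",
    "generate_vertebra_mesh",
    "analytic_vhr",
    "generate_ct_phantom",
    "generate_cohort",
    "NS_MAJOR_DEFAULT",
    "IS_MAIN_DEFAULT",
    "IS_COMP_DEFAULT",
]

_MAX_TILT_DEG = 15.0
_TILT_CLAMP_DEG = 14.5  # rare-tail clamp keeping specs inside their validity range


@dataclass(frozen=True)
class VertebraSpec:
    """Parameters of one synthetic wedged vertebral body.

    ``r_x``/``r_y`` are the lateral/anteroposterior endplate semi-axes (mm),
    ``height`` the mid-axis body height (mm), ``tilt_deg`` the coronal wedge
    angle of the upper endplate about the AP axis (concave side lower),
    ``waist`` the mid-wall radial scale (<1 gives the usual waisted wall).
    """

    r_x: float = 18.0
    r_y: float = 13.5
    height: float = 22.0
    tilt_deg: float = 0.0
    waist: float = 0.92
    resolution: int = 48
    concave_side: str = "left"
    level: str = "L1"

    def __post_init__(self):
        if min(self.r_x, self.r_y, self.height) <= 0:
            raise ValueError("semi-axes and height must be positive")
        if abs(self.tilt_deg) >= _MAX_TILT_DEG:
            raise ValueError(f"|tilt| must be < {_MAX_TILT_DEG} degrees")
        if self.resolution < 16:
            raise ValueError("resolution must be at least 16 segments")
        if self.concave_side not in ("left", "right"):
            raise ValueError("concave_side must be 'left' or 'right'")


def _upper_z(spec: VertebraSpec, x: np.ndarray | float):
    """Height of the (sheared) upper endplate plane above lateral offset x."""
    sign = 1.0 if spec.concave_side == "left" else -1.0
    return spec.height + sign * math.tan(math.radians(spec.tilt_deg)) * x


def generate_vertebra_mesh(spec: VertebraSpec, seed: int = 0) -> VertebralBodyModel:
    """Watertight labeled wedged-vertebra mesh with foramen-proxy landmarks.

    The geometry is fully determined by ``spec``; ``seed`` is accepted for
    interface symmetry with the stochastic generators.  Landmarks a and b sit
    at the posterior rim midline of the upper/lower endplates (no posterior
    elements are meshed, so these stand in for the anterior edges of the
    vertebral foramen).
    """
    n = int(spec.resolution)
    n += (-n) % 4  # keep the 270-degree (posterior midline) node on the grid
    theta = 2.0 * np.pi * np.arange(n) / n
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    s_values = (0.25, 0.5, 0.75)
    vertices = [np.zeros((1, 3))]  # bottom center
    regions = [np.full(1, REGION_LOWER)]

    bottom_ring = np.column_stack([spec.r_x * cos_t, spec.r_y * sin_t, np.zeros(n)])
    vertices.append(bottom_ring)
    regions.append(np.full(n, REGION_LOWER))

    z_top = _upper_z(spec, spec.r_x * cos_t)
    for s in s_values:
        w = 1.0 - (1.0 - spec.waist) * 4.0 * s * (1.0 - s)
        ring = np.column_stack(
            [w * spec.r_x * cos_t, w * spec.r_y * sin_t, s * z_top]
        )
        vertices.append(ring)
        regions.append(np.full(n, REGION_WALL))

    top_ring = np.column_stack([spec.r_x * cos_t, spec.r_y * sin_t, z_top])
    vertices.append(top_ring)
    regions.append(np.full(n, REGION_UPPER))
    vertices.append(np.array([[0.0, 0.0, spec.height]]))  # top center
    regions.append(np.full(1, REGION_UPPER))

    V = np.vstack(vertices)
    region = np.concatenate(regions)

    ring_starts = [1 + k * n for k in range(2 + len(s_values))]
    c_bot, c_top = 0, len(V) - 1
    faces = []
    idx = np.arange(n)
    nxt = (idx + 1) % n
    # bottom cap, outward normal pointing down
    faces.append(np.column_stack([np.full(n, c_bot), ring_starts[0] + nxt, ring_starts[0] + idx]))
    # wall bands
    for lo, hi in zip(ring_starts[:-1], ring_starts[1:]):
        a, a2 = lo + idx, lo + nxt
        b, b2 = hi + idx, hi + nxt
        faces.append(np.column_stack([a, a2, b2]))
        faces.append(np.column_stack([a, b2, b]))
    # top cap, outward normal pointing up
    top0 = ring_starts[-1]
    faces.append(np.column_stack([np.full(n, c_top), top0 + idx, top0 + nxt]))
    mesh = TriMesh(V, np.vstack(faces), region)

    j = 3 * n // 4  # theta = 270 degrees: posterior rim midline
    landmark_a = top_ring[j]
    landmark_b = bottom_ring[j]
    return VertebralBodyModel(
        mesh=mesh,
        landmark_a=landmark_a,
        landmark_b=landmark_b,
        level=spec.level,
        concave_side=spec.concave_side,
    )


def analytic_vhr(spec: VertebraSpec) -> np.ndarray:
    """Closed-form (anterior, middle, posterior) height-ratio triplet of the
    wedged geometry; the independent oracle for the mesh pipeline."""
    t = math.tan(math.radians(spec.tilt_deg))
    x_mid = spec.r_x
    x_ap = spec.r_x * spec.r_y / math.hypot(spec.r_x, spec.r_y)

    def ratio(x: float) -> float:
        num = spec.height - x * t
        den = spec.height + x * t
        if num <= 0 or den <= 0:
            raise ValueError("degenerate collapse: tilt too large for the body size")
        return num / den

    r_ap = ratio(x_ap)
    return np.array([r_ap, ratio(x_mid), r_ap])


def solve_tilt_for_middle_vhr(vhr_middle: float, r_x: float, height: float) -> float:
    """Coronal tilt (degrees) whose middle height ratio equals ``vhr_middle``
    for the given lateral semi-axis and height.  Clamped to the generator's
    validity range (|tilt| < 15 degrees); the clamp engages only for draws
    several SDs below the group means."""
    if vhr_middle <= 0:
        raise ValueError("middle VHR must be positive")
    t = height * (1.0 - vhr_middle) / (r_x * (1.0 + vhr_middle))
    tilt = math.degrees(math.atan(t))
    return float(np.clip(tilt, -_TILT_CLAMP_DEG, _TILT_CLAMP_DEG))


# ---------------------------------------------------------------------------
# CT phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoidal vertebral-body CT phantom: trabecular core with Gaussian
    HU, cortical shell, air background."""

    semi_axes: tuple[float, float, float] = (16.0, 13.0, 11.0)
    shell_mm: float = 2.0
    trabecular_hu: float = 139.0
    trabecular_sd: float = 33.3
    cortical_hu: float = 1000.0
    background_hu: float = -1000.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    padding_mm: float = 4.0

    def __post_init__(self):
        if min(self.semi_axes) <= 0 or min(self.spacing) <= 0:
            raise ValueError("semi-axes and spacing must be positive")
        if self.shell_mm < max(self.spacing):
            raise ValueError("cortical shell must be at least one voxel thick")
        if min(self.semi_axes) - self.shell_mm <= 0:
            raise ValueError("shell thickness leaves no trabecular core")
        if self.trabecular_sd < 0:
            raise ValueError("trabecular SD must be non-negative")

    @property
    def inner_semi_axes(self) -> tuple[float, float, float]:
        return tuple(a - self.shell_mm for a in self.semi_axes)


def generate_ct_phantom(spec: PhantomSpec, seed: int = 0):
    """Seeded (CTVolume, BodyMask) pair realizing ``spec``.

    The body is centered on a voxel center at the world origin; grid
    dimensions are odd so that center exists exactly.
    """
    from .densitometry import (
        LABEL_CORTICAL,
        LABEL_OUTSIDE,
        LABEL_TRABECULAR,
        BodyMask,
        CTVolume,
    )

    spacing = np.asarray(spec.spacing, dtype=float)
    dims = np.ceil(2.0 * (np.asarray(spec.semi_axes) + spec.padding_mm) / spacing)
    dims = dims.astype(int) | 1  # force odd
    origin = -0.5 * (dims - 1) * spacing
    axes_mm = [origin[k] + np.arange(dims[k]) * spacing[k] for k in range(3)]

    def ellipsoid_field(semi):
        return (
            (axes_mm[0][:, None, None] / semi[0]) ** 2
            + (axes_mm[1][None, :, None] / semi[1]) ** 2
            + (axes_mm[2][None, None, :] / semi[2]) ** 2
        )

    u_out = ellipsoid_field(spec.semi_axes)
    u_in = ellipsoid_field(spec.inner_semi_axes)
    labels = np.full(tuple(dims), LABEL_OUTSIDE, dtype=np.int16)
    labels[u_out <= 1.0] = LABEL_CORTICAL
    labels[u_in <= 1.0] = LABEL_TRABECULAR

    rng = np.random.default_rng(seed)
    hu = np.full(tuple(dims), spec.background_hu, dtype=float)
    hu[labels == LABEL_CORTICAL] = spec.cortical_hu
    n_trab = int((labels == LABEL_TRABECULAR).sum())
    if n_trab == 0:
        raise ValueError("phantom has an empty trabecular region")
    hu[labels == LABEL_TRABECULAR] = rng.normal(
        spec.trabecular_hu, spec.trabecular_sd, n_trab
    )
    return CTVolume(hu, spacing, origin), BodyMask(labels, spacing, origin)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveParams:
    """Generating distributions for one curve type (means and SDs)."""

    name: str
    vhr_mean: tuple[float, float, float]
    vhr_sd: tuple[float, float, float]
    hu_mean: float
    hu_sd: float
    cobb_erect_mean: float
    cobb_erect_sd: float
    cobb_bending_mean: float
    cobb_bending_sd: float
    apical_levels: tuple[str, ...]


NS_MAJOR_DEFAULT = CurveParams(
    name="NS_major",
    vhr_mean=(0.970, 0.934, 0.958),
    vhr_sd=(0.048, 0.081, 0.043),
    hu_mean=139.0,
    hu_sd=33.3,
    cobb_erect_mean=73.0,
    cobb_erect_sd=16.8,
    cobb_bending_mean=31.8,
    cobb_bending_sd=13.9,
    apical_levels=("T12", "L1", "L2", "L3"),
)

IS_MAIN_DEFAULT = CurveParams(
    name="IS_main",
    vhr_mean=(0.897, 0.832, 0.883),
    vhr_sd=(0.072, 0.086, 0.059),
    hu_mean=220.1,
    hu_sd=25.2,
    cobb_erect_mean=64.2,
    cobb_erect_sd=16.1,
    cobb_bending_mean=31.5,
    cobb_bending_sd=8.8,
    apical_levels=("T8", "T9", "T10", "T12", "L1"),
)

IS_COMP_DEFAULT = CurveParams(
    name="IS_comp",
    vhr_mean=(0.968, 0.942, 0.967),
    vhr_sd=(0.045, 0.067, 0.046),
    hu_mean=209.5,
    hu_sd=23.5,
    cobb_erect_mean=36.8,
    cobb_erect_sd=13.3,
    cobb_bending_mean=4.5,
    cobb_bending_sd=10.8,
    apical_levels=("T3", "T6", "T7", "L2", "L3", "L4"),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study-level generating conditions: group sizes and distributions.

    Defaults reproduce the reported cohorts: 12 NS patients with one major
    curve and 13 IS patients with a main and a compensatory curve, three
    vertebrae (apical and adjacent) per curve — 36 and 78 vertebral models.
    """

    n_ns: int = 12
    n_is: int = 13
    ns_major: CurveParams = NS_MAJOR_DEFAULT
    is_main: CurveParams = IS_MAIN_DEFAULT
    is_comp: CurveParams = IS_COMP_DEFAULT
    age_ns: tuple[float, float] = (12.9, 1.1)
    age_is: tuple[float, float] = (12.1, 1.3)
    vhr_bounds: tuple[float, float] = (0.5, 1.1)
    r_x_range: tuple[float, float] = (16.0, 20.0)
    body_aspect: float = 0.75  # r_y / r_x
    height_range: tuple[float, float] = (19.0, 24.0)
    waist: float = 0.92
    resolution: int = 48
    patient_effect_sd: float = 0.0  # optional patient-level VHR random effect

    def __post_init__(self):
        if self.n_ns < 1 or self.n_is < 1:
            raise ValueError("group sizes must be at least 1")
        lo, hi = self.vhr_bounds
        if not (0 < lo < hi):
            raise ValueError("infeasible VHR truncation bounds")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        raw = dict(raw)
        curve_overrides = raw.pop("curves", {}) or {}
        known = set(cls.__dataclass_fields__) - {"ns_major", "is_main", "is_comp"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        defaults = {
            "ns_major": NS_MAJOR_DEFAULT,
            "is_main": IS_MAIN_DEFAULT,
            "is_comp": IS_COMP_DEFAULT,
        }
        for key, base in defaults.items():
            ov = curve_overrides.pop(key, None)
            if ov is None:
                kwargs[key] = base
                continue
            bad = set(ov) - set(CurveParams.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown curve config keys for {key}: {sorted(bad)}")
            ov = {k: tuple(v) if isinstance(v, list) else v for k, v in ov.items()}
            kwargs[key] = replace(base, **ov)
        if curve_overrides:
            raise ValueError(f"unknown curve names: {sorted(curve_overrides)}")
        return cls(**kwargs)


@dataclass
class VertebraRecord:
    level: str
    drawn_vhr: np.ndarray  # the independent per-part draws
    realized_vhr: np.ndarray  # ratios the single-tilt geometry realizes
    spec: VertebraSpec
    hu: float
    model: VertebralBodyModel | None = None


@dataclass
class CurveRecord:
    curve_id: str
    name: str  # NS_major / IS_main / IS_comp
    cobb_erect: float
    cobb_bending: float
    apical_level: str
    concave_side: str
    vertebrae: list[VertebraRecord] = field(default_factory=list)

    @property
    def fi_percent(self) -> float:
        return flexibility_index(self.cobb_erect, self.cobb_bending)

    @property
    def hu_mean(self) -> float:
        return float(np.mean([v.hu for v in self.vertebrae]))


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # 'NS' or 'IS'
    age: float
    curves: list[CurveRecord] = field(default_factory=list)


@dataclass
class Cohort:
    spec: CohortSpec
    seed: int
    patients: list[PatientRecord] = field(default_factory=list)

    def iter_vertebrae(self):
        for p in self.patients:
            for c in p.curves:
                for v in c.vertebrae:
                    yield p, c, v

    def model_counts(self) -> dict[str, int]:
        counts = {"NS": 0, "IS": 0}
        for p, _, _ in self.iter_vertebrae():
            counts[p.group] += 1
        return counts

    def measure(self) -> pd.DataFrame:
        """Run the mesh measurement pipeline on every generated model."""
        rows = []
        for p, c, v in self.iter_vertebrae():
            if v.model is None:
                raise ValueError("cohort was generated without meshes")
            res = measure_vertebra(v.model)
            rows.append(
                {
                    "patient": p.patient_id,
                    "group": p.group,
                    "curve": c.name,
                    "curve_id": c.curve_id,
                    "level": v.level,
                    "vhr_ant": res.vhr_anterior,
                    "vhr_mid": res.vhr_middle,
                    "vhr_post": res.vhr_posterior,
                    "hu": v.hu,
                }
            )
        return pd.DataFrame(rows)

    def to_frames(self, source: str = "realized") -> dict[str, pd.DataFrame]:
        """Tidy DataFrames (vertebrae, curves, patients) for the statistics.

        ``source`` selects which triplet fills the ``vhr_*`` columns:
        ``"realized"`` (what the geometry — hence the pipeline — yields) or
        ``"drawn"`` (the independent per-part draws).
        """
        if source not in ("realized", "drawn"):
            raise ValueError("source must be 'realized' or 'drawn'")
        vrows, crows, prows = [], [], []
        for p in self.patients:
            prows.append({"patient": p.patient_id, "group": p.group, "age": p.age})
            for c in p.curves:
                crows.append(
                    {
                        "patient": p.patient_id,
                        "group": p.group,
                        "curve": c.name,
                        "curve_id": c.curve_id,
                        "apical_level": c.apical_level,
                        "cobb_erect": c.cobb_erect,
                        "cobb_bending": c.cobb_bending,
                        "fi_percent": c.fi_percent,
                        "hu": c.hu_mean,
                    }
                )
                for v in c.vertebrae:
                    trip = v.realized_vhr if source == "realized" else v.drawn_vhr
                    vrows.append(
                        {
                            "patient": p.patient_id,
                            "group": p.group,
                            "curve": c.name,
                            "curve_id": c.curve_id,
                            "level": v.level,
                            "vhr_ant": trip[0],
                            "vhr_mid": trip[1],
                            "vhr_post": trip[2],
                            "drawn_ant": v.drawn_vhr[0],
                            "drawn_mid": v.drawn_vhr[1],
                            "drawn_post": v.drawn_vhr[2],
                            "tilt_deg": v.spec.tilt_deg,
                            "hu": v.hu,
                        }
                    )
        return {
            "vertebrae": pd.DataFrame(vrows),
            "curves": pd.DataFrame(crows),
            "patients": pd.DataFrame(prows),
        }


def _truncated_normal(rng, mean, sd, bounds, max_tries: int = 10000) -> float:
    lo, hi = bounds
    if sd == 0:
        if not (lo < mean <= hi):
            raise ValueError("infeasible truncation bounds for a zero-SD draw")
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    raise ValueError("infeasible truncation bounds: rejection sampling failed")


def _adjacent_levels(apical: str) -> tuple[str, str, str]:
    k = level_order(apical)
    if k == 0 or k == len(LEVELS) - 1:
        raise ValueError(f"apical level {apical} has no adjacent vertebra on one side")
    return LEVELS[k - 1], apical, LEVELS[k + 1]


def _make_curve(
    rng: np.random.Generator,
    params: CurveParams,
    spec: CohortSpec,
    curve_id: str,
    with_meshes: bool,
    patient_shift: float = 0.0,
) -> CurveRecord:
    # Cobb pair: redraw until 0 <= bending <= erect.
    while True:
        erect = rng.normal(params.cobb_erect_mean, params.cobb_erect_sd)
        bending = rng.normal(params.cobb_bending_mean, params.cobb_bending_sd)
        if erect > 0 and 0.0 <= bending <= erect:
            break
    apical = str(rng.choice(list(params.apical_levels)))
    concave_side = str(rng.choice(["left", "right"]))
    curve = CurveRecord(
        curve_id=curve_id,
        name=params.name,
        cobb_erect=float(erect),
        cobb_bending=float(bending),
        apical_level=apical,
        concave_side=concave_side,
    )
    for level in _adjacent_levels(apical):
        drawn = np.array(
            [
                _truncated_normal(
                    rng, params.vhr_mean[k] + patient_shift, params.vhr_sd[k],
                    spec.vhr_bounds,
                )
                for k in range(3)
            ]
        )
        r_x = rng.uniform(*spec.r_x_range)
        height = rng.uniform(*spec.height_range)
        tilt = solve_tilt_for_middle_vhr(drawn[1], r_x, height)
        vspec = VertebraSpec(
            r_x=r_x,
            r_y=spec.body_aspect * r_x,
            height=height,
            tilt_deg=tilt,
            waist=spec.waist,
            resolution=spec.resolution,
            concave_side=concave_side,
            level=level,
        )
        record = VertebraRecord(
            level=level,
            drawn_vhr=drawn,
            realized_vhr=analytic_vhr(vspec),
            spec=vspec,
            hu=float(rng.normal(params.hu_mean, params.hu_sd)),
            model=generate_vertebra_mesh(vspec) if with_meshes else None,
        )
        curve.vertebrae.append(record)
    return curve


def generate_cohort(
    spec: CohortSpec, seed: int, with_meshes: bool = True
) -> Cohort:
    """Realize a full NS + IS cohort from ``spec``.

    Deterministic for a fixed master seed; each patient consumes an
    independent substream so group sizes can change without reshuffling other
    patients.  ``with_meshes=False`` skips mesh synthesis (the analytic
    realized ratios are still computed) for replication studies.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(spec.n_ns + spec.n_is)
    cohort = Cohort(spec=spec, seed=seed)
    for i in range(spec.n_ns):
        rng = np.random.default_rng(children[i])
        pid = f"NS{i + 1:03d}"
        shift = rng.normal(0.0, spec.patient_effect_sd) if spec.patient_effect_sd else 0.0
        patient = PatientRecord(pid, "NS", float(rng.normal(*spec.age_ns)))
        patient.curves.append(
            _make_curve(rng, spec.ns_major, spec, f"{pid}-major", with_meshes, shift)
        )
        cohort.patients.append(patient)
    for j in range(spec.n_is):
        rng = np.random.default_rng(children[spec.n_ns + j])
        pid = f"IS{j + 1:03d}"
        shift = rng.normal(0.0, spec.patient_effect_sd) if spec.patient_effect_sd else 0.0
        patient = PatientRecord(pid, "IS", float(rng.normal(*spec.age_is)))
        patient.curves.append(
            _make_curve(rng, spec.is_main, spec, f"{pid}-main", with_meshes, shift)
        )
        patient.curves.append(
            _make_curve(rng, spec.is_comp, spec, f"{pid}-comp", with_meshes, shift)
        )
        cohort.patients.append(patient)
    return cohort
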