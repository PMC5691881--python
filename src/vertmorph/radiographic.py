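"""Coronal radiograph indices: Cobb angle, flexibility index, curve roles.

The Cobb angle of a curve is the angle between the upper endplate line of the
upper end-vertebra and the lower endplate line of the lower end-vertebra on a
coronal radiograph.  The flexibility index (FI) is the percent reduction of
the Cobb angle from the erect (standing or sitting) film to the supine
bending film:

    FI(%) = (Cobb_erect - Cobb_bending) / Cobb_erect * 100

A curve whose bending Cobb stays at or above a residual threshold (25° by the
usual Lenke convention, configurable) is structural; the structural curve is
the main curve, and if no curve is structural the one with the greater erect
Cobb is.  Remaining curves are compensatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EndplateLine2D",
    "CurveMeasurement",
    "CurveRole",
    "cobb_angle",
    "endplate_lines_from_cobb",
    "flexibility_index",
    "classify_structural",
    "assign_main_compensatory",
    "level_order",
    "LEVELS",
]

#: Thoracic and lumbar levels in cranial-to-caudal order.
LEVELS = tuple(f"T{i}" for i in range(1, 13)) + tuple(f"L{i}" for i in range(1, 6))

DEFAULT_STRUCTURAL_THRESHOLD_DEG = 25.0


def level_order(level: str) -> int:
    """Cranial-to-caudal ordinal of a vertebral level label (T1=0 ... L5=16)."""
    try:
        return LEVELS.index(level)
    except ValueError:
        raise ValueError(f"unknown vertebral level {level!r}") from None


@dataclass(frozen=True)
class EndplateLine2D:
    """Endplate line on a coronal radiograph, defined by two points (mm)."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def direction(self) -> np.ndarray:
        d = np.asarray(self.p1, dtype=float) - np.asarray(self.p0, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("degenerate endplate line: the two points coincide")
        return d / n


@dataclass
class CurveMeasurement:
    cobb_erect: float
    cobb_bending: float
    apical_level: str = ""

    def __post_init__(self):
        if self.cobb_erect < 0 or self.cobb_bending < 0:
            raise ValueError("Cobb angles must be non-negative")


@dataclass
class CurveRole:
    structural: bool
    role: str  # 'major', 'main' or 'compensatory'


def cobb_angle(upper: EndplateLine2D, lower: EndplateLine2D) -> float:
    """Acute angle between two endplate lines, degrees in [0, 90]."""
    c = abs(float(upper.direction() @ lower.direction()))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def endplate_lines_from_cobb(angle_deg: float) -> tuple[EndplateLine2D, EndplateLine2D]:
    """Two endplate lines with slopes +/- tan(angle/2), whose Cobb angle is
    exactly ``angle_deg`` (the inverse construction used for testing)."""
    half = np.deg2rad(angle_deg / 2.0)
    s = float(np.tan(half))
    return (
        EndplateLine2D((0.0, 0.0), (1.0, s)),
        EndplateLine2D((0.0, 0.0), (1.0, -s)),
    )


def flexibility_index(cobb_erect: float, cobb_bending: float) -> float:
    """Percent Cobb-angle reduction from the erect to the bending film."""
    if cobb_erect <= 0:
        raise ValueError("erect Cobb angle must be positive to compute FI")
    return (cobb_erect - cobb_bending) / cobb_erect * 100.0


def classify_structural(
    cobb_bending: float, threshold: float = DEFAULT_STRUCTURAL_THRESHOLD_DEG
) -> bool:
    """Structural iff the bending Cobb fails to correct below ``threshold``
    (boundary inclusive)."""
    if cobb_bending < 0:
        raise ValueError("bending Cobb must be non-negative")
    return cobb_bending >= threshold


def assign_main_compensatory(
    curves: list[CurveMeasurement],
    threshold: float = DEFAULT_STRUCTURAL_THRESHOLD_DEG,
) -> list[CurveRole]:
    """Role assignment within one patient.

    A single curve is the major curve.  With several curves, structural
    curves take precedence for the main role; the main curve is the one with
    the largest erect Cobb (ties broken toward the more caudal apex) among
    the structural curves, or among all curves when none is structural.
    """
    if not curves:
        raise ValueError("no curves to classify")
    flags = [classify_structural(c.cobb_bending, threshold) for c in curves]
    if len(curves) == 1:
        return [CurveRole(flags[0], "major")]

    candidates = [i for i, f in enumerate(flags) if f] or list(range(len(curves)))

    def rank(i: int):
        caudal = level_order(curves[i].apical_level) if curves[i].apical_level else -1
        return (curves[i].cobb_erect, caudal)

    main_idx = max(candidates, key=rank)
    return [
        CurveRole(flags[i], "main" if i == main_idx else "compensatory")
        for i in range(len(curves))
    ]
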