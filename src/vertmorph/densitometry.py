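"""Spherical-ROI Hounsfield-unit densitometry of vertebral bodies.

The procedure emulates the largest-interior-sphere measurement used on
clinical workstations: the sphere is centered at the per-axis midpoint of the
vertebral body's extents (its center on the axial, coronal and sagittal
planes) and grown until just before it would touch the cortical margin or
leave the body; the mean HU over the voxels whose centers fall inside the
sphere is a surrogate for trabecular bone mineral density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LABEL_OUTSIDE",
    "LABEL_TRABECULAR",
    "LABEL_CORTICAL",
    "CTVolume",
    "BodyMask",
    "SphericalROI",
    "body_center",
    "largest_interior_sphere",
    "mean_hu",
    "curve_hu",
    "mask_from_hu_threshold",
]

LABEL_OUTSIDE = 0
LABEL_TRABECULAR = 1
LABEL_CORTICAL = 2


@dataclass
class CTVolume:
    """Scalar HU grid.  Voxel ``(i, j, k)`` has its center at
    ``origin + (i, j, k) * spacing`` (mm, axis-aligned)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        if self.spacing.shape != (3,) or (self.spacing <= 0).any():
            raise ValueError("spacing must be 3 positive values (mm)")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")
        if not np.isfinite(self.data).all():
            raise ValueError("HU values must be finite")


@dataclass
class BodyMask:
    """Per-voxel labels 0=outside, 1=trabecular, 2=cortical on a CT grid."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-dimensional")

    def matches_grid(self, vol: CTVolume, tol: float = 1e-6) -> bool:
        return (
            self.labels.shape == vol.data.shape
            and np.allclose(self.spacing, vol.spacing, atol=tol)
            and np.allclose(self.origin, vol.origin, atol=tol)
        )


@dataclass
class SphericalROI:
    center: np.ndarray
    radius: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


def _voxel_centers_mm(idx: np.ndarray, mask: BodyMask) -> np.ndarray:
    return mask.origin + idx * mask.spacing


def body_center(mask: BodyMask) -> np.ndarray:
    """Per-axis midpoint of the body's (trabecular + cortical) extents, mm."""
    idx = np.argwhere(mask.labels != LABEL_OUTSIDE)
    if len(idx) == 0:
        raise ValueError("mask contains no vertebral-body voxels")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return mask.origin + 0.5 * (lo + hi) * mask.spacing


def largest_interior_sphere(mask: BodyMask, center) -> SphericalROI:
    """Largest sphere around ``center`` that excludes the cortical margin.

    Radius = distance from the center to the nearest non-trabecular voxel
    center, minus half the largest voxel spacing as a safety margin, floored
    at one voxel (with a warning when the floor engages).
    """
    center = np.asarray(center, dtype=float)
    nearest_idx = np.round((center - mask.origin) / mask.spacing).astype(int)
    if (nearest_idx < 0).any() or (nearest_idx >= mask.labels.shape).any():
        raise ValueError("sphere center lies outside the mask grid")
    if mask.labels[tuple(nearest_idx)] != LABEL_TRABECULAR:
        raise ValueError("sphere center is not inside the trabecular region")
    blocked = np.argwhere(mask.labels != LABEL_TRABECULAR)
    if len(blocked) == 0:
        raise ValueError("mask has no cortical/outside voxels to bound the sphere")
    d = np.linalg.norm(_voxel_centers_mm(blocked, mask) - center, axis=1)
    margin = 0.5 * float(mask.spacing.max())
    floor = float(mask.spacing.max())
    radius = float(d.min()) - margin
    if radius < floor:
        warnings.warn(
            "sphere center is within one voxel of the cortical margin; "
            "radius floored at one voxel",
            stacklevel=2,
        )
        radius = floor
    return SphericalROI(center, radius)


def _sphere_voxel_mask(vol_shape, spacing, origin, roi: SphericalROI):
    """Boolean in-sphere mask over an index bounding box; returns
    (slices, mask) so callers touch only the sphere's neighborhood."""
    lo = np.floor((roi.center - roi.radius - origin) / spacing).astype(int)
    hi = np.ceil((roi.center + roi.radius - origin) / spacing).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, vol_shape)
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [origin[k] + np.arange(lo[k], hi[k]) * spacing[k] - roi.center[k]
            for k in range(3)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return slices, d2 <= roi.radius**2


def mean_hu(vol: CTVolume, roi: SphericalROI) -> float:
    """Mean HU over voxels whose centers lie inside the sphere."""
    for k in range(3):
        low_edge = vol.origin[k] - 0.5 * vol.spacing[k]
        high_edge = vol.origin[k] + (vol.data.shape[k] - 0.5) * vol.spacing[k]
        if roi.center[k] - roi.radius < low_edge or roi.center[k] + roi.radius > high_edge:
            raise ValueError("spherical ROI extends beyond the volume grid")
    slices, inside = _sphere_voxel_mask(vol.data.shape, vol.spacing, vol.origin, roi)
    values = vol.data[slices][inside]
    if values.size == 0:
        raise ValueError("sphere contains no voxel centers")
    return float(values.mean())


def sphere_voxel_count(vol: CTVolume, roi: SphericalROI) -> int:
    slices, inside = _sphere_voxel_mask(vol.data.shape, vol.spacing, vol.origin, roi)
    return int(inside.sum())


def curve_hu(values) -> tuple[float, float]:
    """Mean and sample SD of per-vertebra HU values for one curve."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no HU values to summarize")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def mask_from_hu_threshold(
    vol: CTVolume, body: np.ndarray, cortical_hu: float = 400.0
) -> BodyMask:
    """Threshold-based mask for volumes without an explicit cortical label:
    voxels of the body at or above ``cortical_hu`` are treated as cortical."""
    body = np.asarray(body, dtype=bool)
    if body.shape != vol.data.shape:
        raise ValueError("body mask shape differs from the volume grid")
    labels = np.zeros(vol.data.shape, dtype=np.int16)
    labels[body] = LABEL_TRABECULAR
    labels[body & (vol.data >= cortical_hu)] = LABEL_CORTICAL
    return BodyMask(labels, vol.spacing, vol.origin)
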