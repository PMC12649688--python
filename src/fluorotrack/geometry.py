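"""Cone-beam projection geometry, point projection and stereo triangulation.

A :class:`ProjectionGeometry` describes one kV imaging chain: a point X-ray
source and a flat detector with orthonormal in-plane axes.  Pixel
coordinates are 0-based with x = column (along ``detector_u_axis``) and
y = row (along ``detector_v_axis``); the detector center maps to pixel
``((width-1)/2, (height-1)/2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProjectionGeometry",
    "DegenerateGeometryError",
    "project_point",
    "triangulate",
    "stereo_pair",
    "read_geometry",
    "write_geometry",
]


class DegenerateGeometryError(ValueError):
    """Raised when rays cannot be intersected or projected meaningfully."""


@dataclass
class ProjectionGeometry:
    source: tuple[float, float, float]
    detector_center: tuple[float, float, float]
    detector_u_axis: tuple[float, float, float]
    detector_v_axis: tuple[float, float, float]
    pixel_pitch: float
    image_size: tuple[int, int]  # (width, height) px

    def __post_init__(self) -> None:
        self.source = tuple(float(c) for c in self.source)
        self.detector_center = tuple(float(c) for c in self.detector_center)
        u = np.asarray(self.detector_u_axis, dtype=np.float64)
        v = np.asarray(self.detector_v_axis, dtype=np.float64)
        if not (np.isclose(np.linalg.norm(u), 1.0) and np.isclose(np.linalg.norm(v), 1.0)):
            raise ValueError("detector axes must be unit vectors")
        if not np.isclose(np.dot(u, v), 0.0, atol=1e-9):
            raise ValueError("detector axes must be orthogonal")
        self.detector_u_axis = tuple(u)
        self.detector_v_axis = tuple(v)
        self.pixel_pitch = float(self.pixel_pitch)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        if min(self.image_size) <= 0:
            raise ValueError("image size must be positive")
        sd = np.asarray(self.detector_center) - np.asarray(self.source)
        if np.linalg.norm(sd) <= 0 or abs(np.dot(sd, self.normal)) < 1e-12:
            raise ValueError("source must be off the detector plane")

    @property
    def normal(self) -> np.ndarray:
        """Detector plane normal (u x v)."""
        return np.cross(self.detector_u_axis, self.detector_v_axis)

    @property
    def principal_point(self) -> tuple[float, float]:
        w, h = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def pixel_to_world(self, x_px: np.ndarray, y_px: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of detector pixel centers."""
        cx, cy = self.principal_point
        u = np.asarray(self.detector_u_axis)
        v = np.asarray(self.detector_v_axis)
        c = np.asarray(self.detector_center)
        du = (np.asarray(x_px, dtype=np.float64) - cx) * self.pixel_pitch
        dv = (np.asarray(y_px, dtype=np.float64) - cy) * self.pixel_pitch
        return c + du[..., None] * u + dv[..., None] * v


def project_point(geom: ProjectionGeometry, point) -> tuple[float, float]:
    """Perspective-project a world point onto the detector, in pixels.

    The source->point ray is intersected with the detector plane.  Points
    at or behind the source have no physical image and raise
    :class:`DegenerateGeometryError`.
    """
    src = np.asarray(geom.source, dtype=np.float64)
    pt = np.asarray(point, dtype=np.float64)
    ray = pt - src
    if np.linalg.norm(ray) < 1e-12:
        raise DegenerateGeometryError("point coincides with the source")
    n = geom.normal
    denom = np.dot(n, ray)
    if abs(denom) < 1e-12:
        raise DegenerateGeometryError("ray is parallel to the detector plane")
    t = np.dot(n, np.asarray(geom.detector_center) - src) / denom
    if t <= 0:
        raise DegenerateGeometryError("point lies behind the source")
    hit = src + t * ray
    rel = hit - np.asarray(geom.detector_center)
    cx, cy = geom.principal_point
    x = float(np.dot(rel, geom.detector_u_axis) / geom.pixel_pitch + cx)
    y = float(np.dot(rel, geom.detector_v_axis) / geom.pixel_pitch + cy)
    return x, y


def _backproject_ray(geom: ProjectionGeometry, p_px) -> tuple[np.ndarray, np.ndarray]:
    pix = geom.pixel_to_world(np.atleast_1d(p_px[0]), np.atleast_1d(p_px[1]))[0]
    src = np.asarray(geom.source, dtype=np.float64)
    d = pix - src
    return src, d / np.linalg.norm(d)


def triangulate(
    geom_a: ProjectionGeometry,
    p_a,
    geom_b: ProjectionGeometry,
    p_b,
    min_angle_deg: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Intersect two back-projected rays; return (3-D point mm, residual mm).

    The rays rarely meet exactly, so the midpoint of their common
    perpendicular segment is returned; the residual is half the segment
    length.  Near-parallel rays (angle below ``min_angle_deg``) cannot be
    intersected stably and raise :class:`DegenerateGeometryError`.
    """
    s1, d1 = _backproject_ray(geom_a, p_a)
    s2, d2 = _backproject_ray(geom_b, p_b)
    cosang = np.clip(abs(np.dot(d1, d2)), 0.0, 1.0)
    if np.degrees(np.arccos(cosang)) < min_angle_deg:
        raise DegenerateGeometryError("stereo rays are near-parallel")
    # Closest points: solve [d1.d1 -d1.d2; d1.d2 -d2.d2] [t1 t2]' = [d1.w; d2.w]
    w = s2 - s1
    a = np.dot(d1, d1)
    b = np.dot(d1, d2)
    c = np.dot(d2, d2)
    det = b * b - a * c
    t1 = (np.dot(d2, w) * b - np.dot(d1, w) * c) / det
    t2 = (np.dot(d2, w) * a - np.dot(d1, w) * b) / det
    p1 = s1 + t1 * d1
    p2 = s2 + t2 * d2
    return (p1 + p2) / 2.0, float(np.linalg.norm(p1 - p2) / 2.0)


def stereo_pair(
    sad: float = 1000.0,
    sdd: float = 1500.0,
    image_size: tuple[int, int] = (256, 256),
    pixel_pitch: float = 0.4,
    angles_deg: tuple[float, float] = (-45.0, 45.0),
) -> tuple[ProjectionGeometry, ProjectionGeometry]:
    """Two oblique kV chains crossing at the isocenter.

    ``sad`` is the source-axis distance and ``sdd`` the source-detector
    distance; each chain lies in the X-Z (LR-AP) room plane, rotated about
    the SI axis by its entry in ``angles_deg``.  The detector v axis points
    along -SI so image rows run superior to inferior.  Defaults are
    configurable placeholders in the style of floor/ceiling-mounted
    fluoroscopy chains; they are not any vendor's calibration.
    """
    geoms = []
    for ang in angles_deg:
        th = np.radians(ang)
        ray = np.array([np.sin(th), 0.0, -np.cos(th)])  # source->isocenter
        src = -sad * ray
        det_c = src + sdd * ray
        u = np.array([np.cos(th), 0.0, np.sin(th)])
        v = np.array([0.0, -1.0, 0.0])
        geoms.append(
            ProjectionGeometry(tuple(src), tuple(det_c), tuple(u), tuple(v), pixel_pitch, image_size)
        )
    return geoms[0], geoms[1]


def write_geometry(geom: ProjectionGeometry, path: str) -> None:
    payload = {
        "source": list(geom.source),
        "detector_center": list(geom.detector_center),
        "detector_u_axis": list(geom.detector_u_axis),
        "detector_v_axis": list(geom.detector_v_axis),
        "pixel_pitch": geom.pixel_pitch,
        "image_size": list(geom.image_size),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_geometry(path: str) -> ProjectionGeometry:
    with open(path) as fh:
        payload = json.load(fh)
    return ProjectionGeometry(
        tuple(payload["source"]),
        tuple(payload["detector_center"]),
        tuple(payload["detector_u_axis"]),
        tuple(payload["detector_v_axis"]),
        float(payload["pixel_pitch"]),
        tuple(payload["image_size"]),
    )
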