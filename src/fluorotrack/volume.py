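"""CT-like volumes in Hounsfield units.

A :class:`CTVolume` is a regular voxel grid with physical spacing and an
origin in room coordinates.  The room frame has its origin at the machine
isocenter with X = left-right (LR), Y = superior-inferior (SI) and
Z = anterior-posterior (AP).  Array axes are ordered (x, y, z) with z the
slice axis; the world position of voxel (i, j, k) center is
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CTVolume",
    "interpolate_slices",
    "dilate_marker",
    "read_volume",
    "write_volume",
]

AIR_HU = -1000.0


@dataclass
class CTVolume:
    """Voxel grid of Hounsfield units with spacing and origin in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive in all axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers_world(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one array axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world-space corners of the voxel-center bounding box."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def centered(self) -> "CTVolume":
        """Copy with the grid translated so its center sits at the isocenter."""
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return replace(self, origin=tuple(-extent / 2.0))


def interpolate_slices(vol: CTVolume) -> CTVolume:
    """Insert the mean of each adjacent slice pair midway along z.

    Doubling the through-plane sampling this way takes n slices at spacing
    s to 2n-1 slices at spacing s/2 (e.g. 2 mm planning-CT slices to 1 mm),
    which improves the fidelity of subsequently rendered radiographs.
    """
    v = vol.values
    nz = v.shape[2]
    if nz < 2:
        raise ValueError("slice interpolation needs at least 2 slices")
    out = np.empty(v.shape[:2] + (2 * nz - 1,), dtype=np.float64)
    out[:, :, 0::2] = v
    out[:, :, 1::2] = 0.5 * (v[:, :, :-1] + v[:, :, 1:])
    sx, sy, sz = vol.spacing
    return CTVolume(out, (sx, sy, sz / 2.0), vol.origin)


def dilate_marker(
    vol: CTVolume,
    center: tuple[float, float, float],
    radius_mm: float = 5.0,
    hu: float = 3000.0,
) -> CTVolume:
    """Inflate a fiducial marker into a high-HU sphere.

    Every voxel whose center lies within ``radius_mm`` of ``center`` (world
    mm) is set to ``hu``; all other voxels are untouched.  A 5 mm radius at
    3000 HU renders as an easily identified circular blob in projections,
    which is how a specific marker is matched between the two stereo views.
    """
    center = np.asarray(center, dtype=np.float64)
    lo, hi = vol.bounds()
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError("marker center lies outside the volume")
    xs = vol.voxel_centers_world(0)[:, None, None]
    ys = vol.voxel_centers_world(1)[None, :, None]
    zs = vol.voxel_centers_world(2)[None, None, :]
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
    out = vol.values.copy()
    out[d2 <= radius_mm**2] = hu
    return CTVolume(out, vol.spacing, vol.origin)


def write_volume(vol: CTVolume, path: str) -> None:
    """Write as NIfTI/MetaImage (by extension) via SimpleITK.

    SimpleITK images are indexed (x, y, z) from buffers ordered (z, y, x),
    so the array is transposed on the way out and back.
    """
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, path)


def read_volume(path: str) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    values = sitk.GetArrayFromImage(img).T
    return CTVolume(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
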