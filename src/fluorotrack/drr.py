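"""Digitally reconstructed radiographs (DRRs) and tumor-label projection.

Rendering casts one ray per detector pixel from the X-ray source through
the pixel center, integrates the linear attenuation coefficient
``mu(HU) = mu_water * (1 + HU/1000)`` (clamped at >= 0) along the ray with
a fixed step, and maps transmission ``exp(-integral)`` linearly so that an
unattenuated ray is full-bright (255).  Air is therefore bright and dense
material dark, matching the transmission convention of clinical
fluoroscopy chains.

Tumor labels are produced by threshold projection: a detector pixel is
labeled positive when its ray visits at least ``min_voxels`` distinct mask
voxels.  "Visited" is defined by the sampled ray walk: sample points are
placed every ``step`` mm (default half the minimum voxel spacing) and each
sample is assigned to its nearest voxel index.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import ProjectionGeometry
from .volume import CTVolume

__all__ = [
    "render_drr",
    "project_label",
    "render_views",
    "clean_label",
    "elliptical_footprint",
    "standard_background_mask",
    "apply_sb",
    "to_uint8",
    "MU_WATER",
]

MU_WATER = 0.02  # 1/mm, ~100 kV effective; only relative attenuation matters
_CHUNK = 4096  # rays per block, bounds peak memory of the sample grid


def to_uint8(frame: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round to 8-bit."""
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def _ray_bundle(vol: CTVolume, geom: ProjectionGeometry):
    """Source, unit directions, and entry/exit parameters for all pixels."""
    w, h = geom.image_size
    ys, xs = np.mgrid[0:h, 0:w]
    pix = geom.pixel_to_world(xs.ravel(), ys.ravel())
    src = np.asarray(geom.source, dtype=np.float64)
    d = pix - src
    norms = np.linalg.norm(d, axis=1)
    d /= norms[:, None]
    # Bounding box expanded half a voxel so nearest-voxel assignment covers
    # the full extent of edge voxels.
    lo, hi = vol.bounds()
    half = np.asarray(vol.spacing) / 2.0
    lo = lo - half + 1e-9
    hi = hi + half - 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t1 = (lo[None, :] - src[None, :]) * inv
        t2 = (hi[None, :] - src[None, :]) * inv
    tnear = np.maximum(np.minimum(t1, t2).max(axis=1), 0.0)
    tfar = np.maximum(t1, t2).min(axis=1)
    tfar = np.where(np.isnan(tfar), -1.0, tfar)
    tnear = np.where(np.isnan(tnear), 0.0, tnear)
    return src, d, tnear, tfar


def _trace(
    vol: CTVolume,
    geom: ProjectionGeometry,
    step: float | None,
    mu_water: float | None,
    mask_values: np.ndarray | None,
    min_voxels: int,
):
    """Shared single-pass ray engine for DRR and/or label projection."""
    if step is None:
        step = min(vol.spacing) / 2.0
    if step <= 0:
        raise ValueError("ray step must be positive")
    src, dirs, tnear, tfar = _ray_bundle(vol, geom)
    n_rays = dirs.shape[0]
    tlen = np.maximum(tfar - tnear, 0.0)
    integral = np.zeros(n_rays) if mu_water is not None else None
    counts = np.zeros(n_rays, dtype=np.int64) if mask_values is not None else None

    mu_vol = None
    if mu_water is not None:
        mu_vol = np.maximum(mu_water * (1.0 + vol.values / 1000.0), 0.0)

    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    shape = np.asarray(vol.shape)

    for start in range(0, n_rays, _CHUNK):
        sl = slice(start, start + _CHUNK)
        tl = tlen[sl]
        n_hit = tl > 0
        if not np.any(n_hit):
            continue
        n_steps = int(np.ceil(tl.max() / step))
        seg_start = np.arange(n_steps) * step
        # midpoint samples every `step` mm; the trailing partial segment is
        # weighted by its true remaining length
        ts = tnear[sl, None] + seg_start[None, :] + step / 2.0
        weights = np.clip(tl[:, None] - seg_start[None, :], 0.0, step)
        pts = src[None, None, :] + dirs[sl, None, :] * ts[..., None]
        frac = (pts - origin) / spacing  # fractional voxel indices
        if mu_vol is not None:
            vals = ndimage.map_coordinates(
                mu_vol, frac.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
            ).reshape(weights.shape)
            integral[sl] = (vals * weights).sum(axis=1)
        if mask_values is not None:
            idx = np.floor(frac + 0.5).astype(np.int64)
            valid = (weights > 0) & np.all((idx >= 0) & (idx < shape), axis=-1)
            idx_c = np.clip(idx, 0, shape - 1)
            inmask = mask_values[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]] & valid
            # a straight ray never re-enters a voxel, so distinct visited
            # voxels = entry events (index changed from previous sample)
            changed = np.ones_like(inmask)
            changed[:, 1:] = np.any(idx[:, 1:, :] != idx[:, :-1, :], axis=-1)
            counts[sl] = (inmask & changed).sum(axis=1)
    return integral, counts


def render_drr(
    vol: CTVolume,
    geom: ProjectionGeometry,
    mu_water: float = MU_WATER,
    step: float | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Render a cone-beam DRR of ``vol`` on the detector of ``geom``.

    Rays that miss the volume see no attenuation and render full-bright.
    Returns a (height, width) uint8 frame, or float64 in [0, 255] when
    ``quantize`` is off (useful for sub-level numeric checks).
    """
    integral, _ = _trace(vol, geom, step, mu_water, None, 0)
    w, h = geom.image_size
    frame = 255.0 * np.exp(-integral).reshape(h, w)
    return to_uint8(frame) if quantize else frame


def project_label(
    mask_vol: CTVolume,
    geom: ProjectionGeometry,
    min_voxels: int = 7,
    step: float | None = None,
) -> np.ndarray:
    """Threshold-project a binary tumor mask volume onto the detector.

    A pixel is 1 iff its ray passes through at least ``min_voxels``
    distinct mask voxels, which suppresses grazing rays that would inflate
    the projected tumor silhouette.
    """
    mask = np.asarray(mask_vol.values) > 0.5
    _, counts = _trace(mask_vol, geom, step, None, mask, min_voxels)
    w, h = geom.image_size
    return (counts.reshape(h, w) >= min_voxels).astype(bool)


def render_views(
    vol: CTVolume,
    mask_vol: CTVolume | None,
    geom: ProjectionGeometry,
    mu_water: float = MU_WATER,
    min_voxels: int = 7,
    step: float | None = None,
    quantize: bool = True,
):
    """Render a DRR and (optionally) its tumor label in one ray pass.

    The mask volume must share the CT volume's grid (shape, spacing and
    origin); use :func:`project_label` directly for a mask on its own grid.
    """
    mask = None
    if mask_vol is not None:
        same_grid = (
            mask_vol.shape == vol.shape
            and np.allclose(mask_vol.spacing, vol.spacing)
            and np.allclose(mask_vol.origin, vol.origin)
        )
        if not same_grid:
            raise ValueError("mask volume grid differs from the CT volume grid")
        mask = np.asarray(mask_vol.values) > 0.5
    integral, counts = _trace(vol, geom, step, mu_water, mask, min_voxels)
    w, h = geom.image_size
    frame = 255.0 * np.exp(-integral).reshape(h, w)
    if quantize:
        frame = to_uint8(frame)
    label = None if counts is None else (counts.reshape(h, w) >= min_voxels)
    return frame, label


def elliptical_footprint(width: int = 10, height: int = 10) -> np.ndarray:
    """Binary elliptical structuring element on a width x height grid.

    Built directly from the inscribed-ellipse equation so even sizes (such
    as the default 10 x 10) are supported, which off-the-shelf odd-radius
    footprint helpers are not.
    """
    if width <= 0 or height <= 0:
        raise ValueError("footprint size must be positive")
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    yy, xx = np.mgrid[0:height, 0:width]
    return ((xx - cx) / (width / 2.0)) ** 2 + ((yy - cy) / (height / 2.0)) ** 2 <= 1.0


def clean_label(label: np.ndarray, footprint: np.ndarray | None = None) -> np.ndarray:
    """Morphological opening then closing with a 10x10 elliptical element.

    Opening removes small isolated positive specks; closing fills minor
    holes inside the tumor silhouette.
    """
    lab = np.asarray(label) > 0.5
    if footprint is None:
        footprint = elliptical_footprint(10, 10)
    from skimage.morphology import closing, opening

    return closing(opening(lab, footprint), footprint).astype(bool)


def standard_background_mask(size: tuple[int, int]) -> np.ndarray:
    """Standard-background (SB) mask: 1 inside the largest centered circle.

    Fluoroscopic frames have a circular imaging field; zeroing everything
    outside a common inscribed circle standardizes backgrounds across
    frames, DRRs and labels.  Radius is floor(min(W, H)/2) about the
    geometric image center.
    """
    w, h = int(size[0]), int(size[1])
    if w <= 0 or h <= 0:
        raise ValueError("mask size must be positive")
    r = min(w, h) // 2
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def apply_sb(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero all pixels outside the SB mask."""
    frame = np.asarray(frame)
    if frame.shape != mask.shape:
        raise ValueError("frame and SB mask shapes differ")
    return frame * mask.astype(frame.dtype)
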