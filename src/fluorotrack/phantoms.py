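"""Synthetic phantoms, respiratory motion, and rendered stereo sequences.

Everything the rest of the toolkit needs to be exercised without clinical
data: gelatin block/cylinder phantoms with high-HU inserts (the static
targets used for noise characterization), a simple thorax stand-in with
an ellipsoidal tumor and point fiducial markers, a harmonic respiratory
motion model, a Bernoulli-Gaussian noise injector with known parameters,
and a full stereo renderer that produces frame stacks together with their
exact ground-truth trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .degrade import DegradationParams, build_noise_maps, degrade
from .content import ContentCurves
from .drr import render_views, to_uint8
from .geometry import ProjectionGeometry, project_point
from .trajectory import Trajectory2D, Trajectory3D
from .volume import AIR_HU, CTVolume

__all__ = [
    "PhantomSpec",
    "MotionModel",
    "make_block_phantom",
    "make_thorax_phantom",
    "respiratory_displacement",
    "inject_known_noise",
    "render_sequence",
    "RenderedSequence",
    "GELATIN_HU",
    "ALUMINUM_HU",
    "LUNG_HU",
    "TUMOR_HU",
    "MARKER_HU",
]

# Plausible fixed defaults for phantom materials (all configurable).
GELATIN_HU = 0.0
ALUMINUM_HU = 2000.0
LUNG_HU = -800.0
TUMOR_HU = 40.0
MARKER_HU = 3000.0


@dataclass
class PhantomSpec:
    """A gelatin block or cylinder with optional box inserts.

    ``inserts`` are (center mm, extent mm, HU) triples - e.g. aluminum
    slabs of graded thickness embedded to mimic bone.  All coordinates
    are in the phantom frame (phantom centered on the isocenter).
    """

    shape: str = "cube"
    outer_size: float = 60.0
    gelatin_hu: float = GELATIN_HU
    inserts: tuple = ()

    def __post_init__(self) -> None:
        if self.shape not in ("cube", "cylinder"):
            raise ValueError("phantom shape must be 'cube' or 'cylinder'")
        if self.outer_size <= 0:
            raise ValueError("outer size must be positive")
        if not np.isfinite(self.gelatin_hu):
            raise ValueError("HU values must be finite")
        for _, _, hu in self.inserts:
            if not np.isfinite(hu):
                raise ValueError("HU values must be finite")


@dataclass
class MotionModel:
    """Periodic respiratory displacement with harmonics.

    The waveform per axis is the per-axis amplitude times a fundamental
    sinusoid at ``rate_bpm / 60`` Hz plus integer harmonics with the given
    relative amplitudes; defaults (2nd at 0.3, 3rd at 0.1, 20 breaths/min)
    reproduce the typical harmonic structure of respiratory motion.  The
    default amplitudes put most motion on the SI axis, as for lower-lobe
    lung tumors.  An optional cardiac sinusoid can be superimposed.
    """

    rate_bpm: float = 20.0
    amplitude_mm: tuple[float, float, float] = (2.0, 8.0, 3.0)  # LR, SI, AP
    harmonics: tuple = ((2, 0.3), (3, 0.1))
    cardiac_rate_bpm: float | None = None
    cardiac_amplitude_mm: tuple[float, float, float] | None = None
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise ValueError("breathing rate must be positive")
        for order, rel in self.harmonics:
            if int(order) < 2:
                raise ValueError("harmonic orders must be integers >= 2")
            if not 0.0 <= rel <= 1.0:
                raise ValueError("relative harmonic amplitudes must be in [0, 1]")

    @property
    def period_s(self) -> float:
        return 60.0 / self.rate_bpm


def respiratory_displacement(model: MotionModel, t) -> np.ndarray:
    """Displacement (mm, LR/SI/AP) at time(s) ``t`` seconds.

    Zero at t = 0 when ``phase`` is 0; periodic with period 60/rate_bpm s
    whenever the cardiac component is disabled.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    w = 2.0 * np.pi * model.rate_bpm / 60.0
    wave = np.sin(w * t + model.phase)
    for order, rel in model.harmonics:
        wave = wave + rel * np.sin(order * (w * t + model.phase))
    amp = np.asarray(model.amplitude_mm, dtype=np.float64)
    disp = wave[..., None] * amp
    if model.cardiac_rate_bpm is not None and model.cardiac_amplitude_mm is not None:
        wc = 2.0 * np.pi * model.cardiac_rate_bpm / 60.0
        camp = np.asarray(model.cardiac_amplitude_mm, dtype=np.float64)
        disp = disp + np.sin(wc * t)[..., None] * camp
    return disp


def _centered_grid(size_mm, voxel_spacing):
    spacing = np.asarray(voxel_spacing, dtype=np.float64)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    size = np.asarray(size_mm, dtype=np.float64)
    shape = np.maximum(np.floor(size / spacing).astype(int) + 1, 2)
    origin = -(shape - 1) * spacing / 2.0
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    return shape, tuple(origin), xs[:, None, None], ys[None, :, None], zs[None, None, :]


def make_block_phantom(spec: PhantomSpec, voxel_spacing) -> CTVolume:
    """Voxelize a gelatin phantom with its inserts, in air.

    Voxels inside the phantom body get ``gelatin_hu``, inside an insert
    the insert's HU, and outside the phantom -1000 (air).  Every insert
    must lie fully inside the phantom body.
    """
    half = spec.outer_size / 2.0
    margin = 10.0  # mm of air around the phantom
    size_mm = np.full(3, spec.outer_size + 2 * margin)
    shape, origin, xs, ys, zs = _centered_grid(size_mm, voxel_spacing)

    if spec.shape == "cube":
        inside = (np.abs(xs) <= half) & (np.abs(ys) <= half) & (np.abs(zs) <= half)

        def body_contains(lo, hi):
            return np.all(lo >= -half) and np.all(hi <= half)

    else:  # cylinder, axis along z
        inside = (xs**2 + ys**2 <= half**2) & (np.abs(zs) <= half)

        def body_contains(lo, hi):
            corners_r = max(np.hypot(a, b) for a in (lo[0], hi[0]) for b in (lo[1], hi[1]))
            return corners_r <= half and lo[2] >= -half and hi[2] <= half

    values = np.where(inside, spec.gelatin_hu, AIR_HU)
    for center, extent, hu in spec.inserts:
        c = np.asarray(center, dtype=np.float64)
        e = np.asarray(extent, dtype=np.float64)
        if np.any(e <= 0):
            raise ValueError("insert extents must be positive")
        lo, hi = c - e / 2.0, c + e / 2.0
        if not body_contains(lo, hi):
            raise ValueError(f"insert at {tuple(c)} extends outside the phantom body")
        in_box = (
            (np.abs(xs - c[0]) <= e[0] / 2.0)
            & (np.abs(ys - c[1]) <= e[1] / 2.0)
            & (np.abs(zs - c[2]) <= e[2] / 2.0)
        )
        values = np.where(in_box, hu, values)
    return CTVolume(values, tuple(np.asarray(voxel_spacing, dtype=np.float64)), origin)


def make_thorax_phantom(
    tumor_center,
    tumor_radii,
    marker_centers=(),
    voxel_spacing=(2.0, 2.0, 2.0),
    size_mm=(120.0, 120.0, 120.0),
    lung_hu: float = LUNG_HU,
    tumor_hu: float = TUMOR_HU,
    marker_hu: float = MARKER_HU,
):
    """Ellipsoidal soft-tissue tumor plus point markers in lung background.

    Returns ``(volume, tumor_mask_volume, marker_centers)``; the mask is
    exactly the set of voxels whose centers lie inside the ellipsoid.
    Markers are single high-HU voxels (the nearest voxel to each center);
    two markers landing on the same voxel is suspicious geometry and
    warns, but is not an error.
    """
    c = np.asarray(tumor_center, dtype=np.float64)
    r = np.asarray(tumor_radii, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("tumor radii must be positive")
    shape, origin, xs, ys, zs = _centered_grid(size_mm, voxel_spacing)
    lo = np.asarray(origin)
    hi = lo + (shape - 1) * np.asarray(voxel_spacing, dtype=np.float64)
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise ValueError("tumor extends outside the volume")
    mask = (
        ((xs - c[0]) / r[0]) ** 2 + ((ys - c[1]) / r[1]) ** 2 + ((zs - c[2]) / r[2]) ** 2
    ) <= 1.0
    values = np.where(mask, tumor_hu, lung_hu)
    vol = CTVolume(values, tuple(np.asarray(voxel_spacing, dtype=np.float64)), origin)
    occupied: dict[tuple[int, int, int], int] = {}
    markers = []
    for m, center in enumerate(marker_centers):
        mc = np.asarray(center, dtype=np.float64)
        if np.any(mc < lo) or np.any(mc > hi):
            raise ValueError(f"marker {m} lies outside the volume")
        idx = tuple(int(i) for i in np.rint(vol.world_to_index(mc)[0]))
        if idx in occupied:
            warnings.warn(
                f"markers {occupied[idx]} and {m} share voxel {idx}", stacklevel=2
            )
        occupied[idx] = m
        vol.values[idx] = marker_hu
        markers.append(mc)
    mask_vol = CTVolume(mask.astype(np.float64), vol.spacing, vol.origin)
    return vol, mask_vol, markers


def inject_known_noise(
    clean: np.ndarray,
    q_map: np.ndarray,
    a_map: np.ndarray,
    mu: float,
    n_frames: int,
    seed: int,
    clip: bool = True,
) -> np.ndarray:
    """Frames of ``clean`` plus Bernoulli(q) x Normal(mu, a) noise per pixel.

    The ground-truth noise law is fully known, so downstream statistics
    can be checked against closed forms; ``clip=False`` keeps float
    values (exact tests), otherwise frames are clipped to 8 bits.  Frame
    k is drawn from the substream (seed, k) and is reproducible in
    isolation.
    """
    clean = np.asarray(clean, dtype=np.float64)
    q = np.asarray(q_map, dtype=np.float64)
    a = np.asarray(a_map, dtype=np.float64)
    if q.shape != clean.shape or a.shape != clean.shape:
        raise ValueError("q_map/a_map shape must match the clean frame")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q_map values must be probabilities")
    if np.any(a < 0):
        raise ValueError("a_map values must be non-negative")
    frames = np.empty((n_frames,) + clean.shape, dtype=np.float64)
    for k in range(n_frames):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        events = rng.random(clean.shape) < q
        noise = rng.normal(mu, a)
        frames[k] = clean + np.where(events, noise, 0.0)
    if clip:
        return np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    return frames


@dataclass
class RenderedSequence:
    """A rendered stereo sequence with exact ground truth."""

    frames_a: np.ndarray  # (n, H, W) uint8
    frames_b: np.ndarray
    labels_a: np.ndarray  # (n, H, W) bool
    labels_b: np.ndarray
    gt_traj2d_a: Trajectory2D  # projected tumor centroid per view
    gt_traj2d_b: Trajectory2D
    gt_traj3d: Trajectory3D  # tumor centroid path in room mm
    marker_traj_a: list  # one Trajectory2D per marker, view A
    marker_traj_b: list


def render_sequence(
    volume: CTVolume,
    tumor_mask: CTVolume,
    markers,
    motion: MotionModel,
    geometry_pair: tuple[ProjectionGeometry, ProjectionGeometry],
    degradation: DegradationParams | None = None,
    n_frames: int = 30,
    fs: float = 30.0,
    curves: ContentCurves | None = None,
    min_voxels: int = 7,
    step: float | None = None,
) -> RenderedSequence:
    """Render a moving phantom into a stereo frame-stack pair.

    Per frame the whole volume is rigidly displaced by the motion model
    (no deformation), both views are rendered with their tumor labels, and
    optional stochastic degradation is applied with a per-frame/per-view
    seed derived from ``degradation.seed``.  Ground-truth outputs are
    constructed analytically: the 3-D path is the static tumor-mask
    centroid plus the motion displacements, and the 2-D paths and marker
    tracks are its perspective projections.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    geom_a, geom_b = geometry_pair
    mask = np.asarray(tumor_mask.values) > 0.5
    if not mask.any():
        raise ValueError("tumor mask is empty")
    idx = np.argwhere(mask)
    centroid_world = tumor_mask.index_to_world(idx).mean(axis=0)

    t = np.arange(n_frames) / fs
    disp = respiratory_displacement(motion, t)
    gt3d = centroid_world[None, :] + disp

    wa, ha = geom_a.image_size
    wb, hb = geom_b.image_size
    frames_a = np.empty((n_frames, ha, wa), dtype=np.uint8)
    frames_b = np.empty((n_frames, hb, wb), dtype=np.uint8)
    labels_a = np.empty((n_frames, ha, wa), dtype=bool)
    labels_b = np.empty((n_frames, hb, wb), dtype=bool)
    gt2d_a = np.empty((n_frames, 2))
    gt2d_b = np.empty((n_frames, 2))
    markers = [np.asarray(m, dtype=np.float64) for m in markers]
    mk_a = np.empty((len(markers), n_frames, 2))
    mk_b = np.empty((len(markers), n_frames, 2))

    for k in range(n_frames):
        shift = disp[k]
        moved = replace(volume, origin=tuple(np.asarray(volume.origin) + shift))
        moved_mask = replace(tumor_mask, origin=tuple(np.asarray(tumor_mask.origin) + shift))
        for view, geom, frames, labels in (
            (0, geom_a, frames_a, labels_a),
            (1, geom_b, frames_b, labels_b),
        ):
            frame, label = render_views(
                moved, moved_mask, geom, min_voxels=min_voxels, step=step, quantize=False
            )
            if degradation is not None:
                sub = np.random.SeedSequence([degradation.seed, k, view])
                params = replace(
                    degradation, seed=int(sub.generate_state(1)[0] % 2**31)
                )
                frame = degrade(to_uint8(frame), params, curves)
            else:
                frame = to_uint8(frame)
            frames[k] = frame
            labels[k] = label
        gt2d_a[k] = project_point(geom_a, gt3d[k])
        gt2d_b[k] = project_point(geom_b, gt3d[k])
        for m, marker in enumerate(markers):
            pos = marker + shift
            mk_a[m, k] = project_point(geom_a, pos)
            mk_b[m, k] = project_point(geom_b, pos)

    return RenderedSequence(
        frames_a=frames_a,
        frames_b=frames_b,
        labels_a=labels_a,
        labels_b=labels_b,
        gt_traj2d_a=Trajectory2D(gt2d_a, fs=fs),
        gt_traj2d_b=Trajectory2D(gt2d_b, fs=fs),
        gt_traj3d=Trajectory3D(gt3d, fs=fs),
        marker_traj_a=[Trajectory2D(mk_a[m], fs=fs) for m in range(len(markers))],
        marker_traj_b=[Trajectory2D(mk_b[m], fs=fs) for m in range(len(markers))],
    )
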