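"""Tracking pipeline orchestration with pluggable stages.

The clinical workflow is: color-to-gray conversion, optional style
transfer toward the DRR domain, tumor segmentation, centroid trajectory
extraction, mean-position alignment to a reference, low-pass filtering
and stereo triangulation.  The neural stages (style transfer and
segmentation networks) are plugin points with a plain contract - frame in,
frame/mask out; this package ships an identity style-transfer stage and a
classical toy segmenter so the surrounding pipeline is fully testable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .drr import standard_background_mask
from .geometry import ProjectionGeometry
from .trajectory import (
    FilterSpec,
    GradeReport,
    Trajectory2D,
    Trajectory3D,
    align_to_reference,
    error_stats_3d,
    extract_trajectory,
    lowpass,
    rmse_grade,
    trajectory_3d,
)

__all__ = [
    "PipelineConfig",
    "ConfigurationError",
    "TrackingResult",
    "OracleSegmenter",
    "run_tracking",
    "toy_segmenter",
    "grayscale_stage",
    "compare_workflows",
    "SEGMENTERS",
]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A pipeline configuration referenced an unknown stage or plugin."""


def grayscale_stage(frame: np.ndarray) -> np.ndarray:
    """Default color-to-gray conversion: the standard luminance weights.

    The stage contract accepts any drop-in converter (3-channel 8-bit
    frame in, single-channel 8-bit frame out); this default combines
    channels as 0.299 R + 0.587 G + 0.114 B.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("grayscale stage expects a 3-channel frame")
    lum = frame[..., 0] * 0.299 + frame[..., 1] * 0.587 + frame[..., 2] * 0.114
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


def toy_segmenter(frame: np.ndarray, roi: tuple[int, int, int, int] | None = None) -> np.ndarray:
    """Classical tumor segmenter: Otsu on inverted intensity, largest blob.

    Within the ROI (default: the SB circle bounding box), pixels darker
    than the Otsu threshold are candidate tumor (tumors attenuate more
    than lung), the largest connected component is kept and its holes
    filled.  Returns a full-frame boolean mask; an ROI without usable
    contrast yields an empty mask.
    """
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    if roi is None:
        sb = standard_background_mask((w, h))
        ys, xs = np.nonzero(sb)
        roi = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError("ROI lies outside the frame")
    window = frame[y0:y1, x0:x1]
    mask = np.zeros((h, w), dtype=bool)
    if window.max() - window.min() <= 0:
        return mask  # empty-mask signal: nothing to segment
    inverted = window.max() - window
    thr = threshold_otsu(inverted)
    fg = inverted > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = fg & (labels == (1 + int(np.argmax(sizes))))
    mask[y0:y1, x0:x1] = ndimage.binary_fill_holes(largest)
    return mask


# Registry of named segmenter plugins: callable(frame) -> bool mask.
SEGMENTERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "toy": toy_segmenter,
}


class OracleSegmenter:
    """Segmenter plugin that replays precomputed ground-truth masks.

    Used to evaluate the geometric part of the pipeline in isolation: with
    perfect segmentation, any residual tracking error is due to label
    pixelation, filtering and triangulation alone.  The pipeline calls
    ``bind_view`` before each view's frames so the replay stays in sync.
    """

    def __init__(self, masks_a: np.ndarray, masks_b: np.ndarray) -> None:
        self._masks = (np.asarray(masks_a), np.asarray(masks_b))
        self._current = self._masks[0]
        self._i = 0

    def bind_view(self, view: int) -> None:
        self._current = self._masks[view]
        self._i = 0

    def __call__(self, frame: np.ndarray) -> np.ndarray:
        mask = self._current[self._i]
        self._i += 1
        return mask


@dataclass
class PipelineConfig:
    """Stage switches and plugins for one tracking run.

    Segmentation is always on (the pipeline is built around it); the
    style-transfer stage defaults to off and its default plugin is the
    identity, so "without style transfer" and "with an identity
    transfer" runs are byte-identical by construction.
    """

    grayscale: bool = False
    style_transfer: bool = False
    lpf: bool = True
    segmenter: str | Callable = "toy"
    style_transfer_plugin: Callable[[np.ndarray], np.ndarray] | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    fs: float = 30.0
    out_dir: str | None = None
    seed: int = 0


@dataclass
class TrackingResult:
    traj3d: Trajectory3D
    traj2d_a: Trajectory2D
    traj2d_b: Trajectory2D
    grade_a: GradeReport | None
    grade_b: GradeReport | None
    stats: object | None  # ErrorStats3D when a 3-D reference was given
    masks_a: np.ndarray
    masks_b: np.ndarray
    timings_ms: dict


def _resolve_segmenter(spec) -> Callable:
    if callable(spec):
        return spec
    try:
        return SEGMENTERS[spec]
    except KeyError:
        raise ConfigurationError(f"unknown segmenter plugin: {spec!r}") from None


def _run_view(
    stack: np.ndarray, config: PipelineConfig, segment: Callable, timings: dict, view: int
):
    frames = np.asarray(stack)
    if hasattr(segment, "bind_view"):
        segment.bind_view(view)
    if config.grayscale:
        t0 = time.perf_counter()
        frames = np.stack([grayscale_stage(f) for f in frames])
        timings["grayscale"] = timings.get("grayscale", 0.0) + (time.perf_counter() - t0) * 1e3
    if config.style_transfer:
        plugin = config.style_transfer_plugin or (lambda f: f)
        t0 = time.perf_counter()
        frames = np.stack([plugin(f) for f in frames])
        timings["style_transfer"] = (
            timings.get("style_transfer", 0.0) + (time.perf_counter() - t0) * 1e3
        )
    t0 = time.perf_counter()
    masks = np.stack([np.asarray(segment(f), dtype=bool) for f in frames])
    timings["segmentation"] = timings.get("segmentation", 0.0) + (time.perf_counter() - t0) * 1e3
    return masks


def run_tracking(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    config: PipelineConfig,
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    ref2d_a: Trajectory2D | None = None,
    ref2d_b: Trajectory2D | None = None,
    ref3d: Trajectory3D | None = None,
) -> TrackingResult:
    """Run the full stereo tracking workflow on two synchronized stacks.

    Per view: stage chain -> mask sequence -> centroid trajectory ->
    alignment to the 2-D reference (when supplied) -> low-pass filter ->
    stereo triangulation -> 3-D error statistics against ``ref3d`` (when
    supplied).  Stage wall times are logged for information only.
    """
    if len(stack_a) != len(stack_b):
        raise ValueError("stereo stacks have different frame counts")
    segment = _resolve_segmenter(config.segmenter)
    timings: dict = {}
    masks_a = _run_view(stack_a, config, segment, timings, 0)
    masks_b = _run_view(stack_b, config, segment, timings, 1)

    trajs = []
    for masks, ref2d in ((masks_a, ref2d_a), (masks_b, ref2d_b)):
        traj = extract_trajectory(list(masks), fs=config.fs)
        if ref2d is not None:
            traj = align_to_reference(traj, ref2d)
        if config.lpf:
            traj = lowpass(traj, config.filter)
        trajs.append(traj)
    traj_a, traj_b = trajs

    grade_a = rmse_grade(traj_a, ref2d_a) if ref2d_a is not None else None
    grade_b = rmse_grade(traj_b, ref2d_b) if ref2d_b is not None else None
    traj3d = trajectory_3d(traj_a, traj_b, geom_a, geom_b)
    stats = error_stats_3d(traj3d, ref3d) if ref3d is not None else None
    for stage, ms in timings.items():
        log.info("stage %s: %.1f ms total", stage, ms)

    if config.out_dir is not None:
        _persist(config.out_dir, masks_a, masks_b, traj_a, traj_b, traj3d, grade_a, grade_b)
    return TrackingResult(
        traj3d, traj_a, traj_b, grade_a, grade_b, stats, masks_a, masks_b, timings
    )


def _persist(out_dir, masks_a, masks_b, traj_a, traj_b, traj3d, grade_a, grade_b) -> None:
    import imageio.v3 as iio

    from .io import write_trajectory_2d, write_trajectory_3d

    out = Path(out_dir)
    for view, masks in (("a", masks_a), ("b", masks_b)):
        mdir = out / f"masks_{view}"
        mdir.mkdir(parents=True, exist_ok=True)
        for k, mask in enumerate(masks):
            iio.imwrite(mdir / f"{k:05d}.png", (mask * np.uint8(255)))
    write_trajectory_2d(traj_a, out / "trajectory_a.csv")
    write_trajectory_2d(traj_b, out / "trajectory_b.csv")
    write_trajectory_3d(traj3d, out / "trajectory_3d.csv")
    grades = {}
    for view, grade in (("a", grade_a), ("b", grade_b)):
        if grade is not None:
            grades[view] = {
                "rmse_x": grade.rmse_x,
                "rmse_y": grade.rmse_y,
                "E": grade.e,
                "grade": grade.grade,
            }
    with open(out / "grades.json", "w") as fh:
        json.dump(grades, fh, indent=2)


def compare_workflows(dataset, config_a: PipelineConfig, config_b: PipelineConfig):
    """Paired comparison of two workflow configurations on one dataset.

    ``dataset`` is a list of sequence dicts with keys ``name``,
    ``stack_a``, ``stack_b``, ``geom_a``, ``geom_b`` and optional
    ``ref2d_a``/``ref2d_b``/``ref3d``.  Returns a DataFrame with one row
    per sequence holding both configurations' final errors and median
    Euclidean 3-D errors plus their differences.
    """
    import pandas as pd

    if not dataset:
        raise ValueError("dataset is empty")
    rows = []
    for seq in dataset:
        row = {"name": seq.get("name", f"seq{len(rows)}")}
        for tag, config in (("a", config_a), ("b", config_b)):
            res = run_tracking(
                seq["stack_a"],
                seq["stack_b"],
                config,
                seq["geom_a"],
                seq["geom_b"],
                seq.get("ref2d_a"),
                seq.get("ref2d_b"),
                seq.get("ref3d"),
            )
            row[f"E_{tag}"] = max(
                g.e for g in (res.grade_a, res.grade_b) if g is not None
            ) if (res.grade_a or res.grade_b) else np.nan
            row[f"median3d_{tag}"] = (
                res.stats.median_euclidean if res.stats is not None else np.nan
            )
        row["E_diff"] = row["E_b"] - row["E_a"]
        row["median3d_diff"] = row["median3d_b"] - row["median3d_a"]
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["median_E_diff"] = float(np.nanmedian(report["E_diff"]))
    report.attrs["median_median3d_diff"] = float(np.nanmedian(report["median3d_diff"]))
    return report
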