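"""Tumor-motion trajectory extraction, filtering, grading and 3-D errors.

The tumor center in each frame is the centroid of its segmentation mask;
the per-frame centroids form a 2-D trajectory sampled at the acquisition
rate (30 frames/s clinically, so t = frame/30 s).  Because segmentation
jitter injects high-frequency noise well above respiratory/cardiac
frequencies (< 2 Hz), trajectories are smoothed with a fourth-order
zero-phase Butterworth low-pass filter (8 Hz cutoff).  Accuracy against a
reference (e.g. a tracked fiducial marker) is scored by per-axis RMSE
after mean-position alignment; stereo pairs of 2-D trajectories are
triangulated into 3-D room coordinates (LR/SI/AP) for millimeter error
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .geometry import ProjectionGeometry, triangulate

__all__ = [
    "Trajectory2D",
    "Trajectory3D",
    "FilterSpec",
    "GradeReport",
    "EmptyMaskError",
    "centroid",
    "extract_trajectory",
    "lowpass",
    "amplitude_spectrum",
    "peak_frequency",
    "align_to_reference",
    "rmse_grade",
    "grade_for_error",
    "trajectory_3d",
    "error_stats_3d",
    "ErrorStats3D",
    "marker_track_template",
]


class EmptyMaskError(ValueError):
    """A segmentation mask contained no foreground pixels."""


def _points(obj) -> np.ndarray:
    return obj.points if hasattr(obj, "points") else np.asarray(obj, dtype=np.float64)


@dataclass
class Trajectory2D:
    """Per-frame (x, y) pixel positions sampled at ``fs`` Hz."""

    points: np.ndarray
    fs: float = 30.0
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 2:
            raise ValueError("2-D trajectory points must be (N, 2)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.flags is None:
            self.flags = np.zeros(len(self.points), dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != (len(self.points),):
                raise ValueError("flags must have one entry per frame")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.points)) / self.fs


@dataclass
class Trajectory3D:
    """Per-frame (LR, SI, AP) positions in mm sampled at ``fs`` Hz."""

    points: np.ndarray
    fs: float = 30.0
    residuals: np.ndarray | None = None  # triangulation residuals, mm
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 3:
            raise ValueError("3-D trajectory points must be (N, 3)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.flags is None:
            self.flags = np.zeros(len(self.points), dtype=bool)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.points)) / self.fs


@dataclass
class FilterSpec:
    """Butterworth low-pass design: cutoff fc, sampling fs, order, zero-phase."""

    fc: float = 8.0
    fs: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.fc < self.fs / 2:
            raise ValueError("cutoff must satisfy 0 < fc < fs/2")

    def coefficients(self):
        """(b, a) of the digital filter via the bilinear transform."""
        return signal.butter(self.order, self.fc / (0.5 * self.fs), btype="low")


_GRADE_BOUNDS = ((3.0, "Excellent"), (8.0, "High"), (13.0, "Moderate"))


def grade_for_error(e: float) -> str:
    """Map a final 2-D error E (px) to its grade.

    E < 3: Excellent; 3 <= E < 8: High; 8 <= E < 13: Moderate; E >= 13: Low.
    """
    for bound, name in _GRADE_BOUNDS:
        if e < bound:
            return name
    return "Low"


@dataclass
class GradeReport:
    rmse_x: float
    rmse_y: float
    e: float
    grade: str


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (x, y) of a binary mask: mean column and row index."""
    yy, xx = np.nonzero(np.asarray(mask) > 0.5)
    if xx.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return float(xx.mean()), float(yy.mean())


def extract_trajectory(mask_sequence, fs: float = 30.0) -> Trajectory2D:
    """Per-frame mask centroids; empty frames carry the previous position.

    The carried-forward frames are flagged so downstream grading can
    report detection gaps; an empty *first* frame has nothing to carry
    and is an error.
    """
    masks = list(mask_sequence)
    if not masks:
        raise ValueError("mask sequence is empty")
    pts = np.empty((len(masks), 2))
    flags = np.zeros(len(masks), dtype=bool)
    try:
        pts[0] = centroid(masks[0])
    except EmptyMaskError as exc:
        raise EmptyMaskError("first frame mask is empty") from exc
    for k, mask in enumerate(masks[1:], start=1):
        try:
            pts[k] = centroid(mask)
        except EmptyMaskError:
            pts[k] = pts[k - 1]
            flags[k] = True
    return Trajectory2D(pts, fs=fs, flags=flags)


def lowpass(traj, spec: FilterSpec | None = None):
    """Low-pass filter each coordinate of a trajectory.

    Zero-phase mode applies the filter forward and backward (squaring the
    magnitude response and cancelling phase) with reflective edge padding
    of 3x the filter order, so filtered trajectories stay time-aligned
    with the raw data.  Timestamps, flags and sampling rate are unchanged.
    """
    if spec is None:
        spec = FilterSpec(fs=traj.fs)
    if not 0 < spec.fc < traj.fs / 2:
        raise ValueError("cutoff must satisfy 0 < fc < fs/2 for this trajectory")
    spec = replace(spec, fs=traj.fs)
    padlen = 3 * spec.order
    if len(traj) <= padlen:
        raise ValueError(f"trajectory too short to filter (need > {padlen} samples)")
    b, a = spec.coefficients()
    if spec.zero_phase:
        filtered = signal.filtfilt(b, a, traj.points, axis=0, padtype="even", padlen=padlen)
    else:
        filtered = signal.lfilter(b, a, traj.points, axis=0)
    return replace(traj, points=filtered)


def amplitude_spectrum(traj, fs: float | None = None):
    """One-sided FFT amplitude spectrum of each coordinate, mean removed.

    Amplitudes are normalized so a pure sinusoid of amplitude a shows a
    peak of height ~a at its frequency.  Returns (frequencies Hz,
    amplitudes (n_freq, n_coord)).
    """
    pts = _points(traj)
    if fs is None:
        fs = traj.fs
    n = len(pts)
    if n < 8:
        raise ValueError("spectrum needs at least 8 samples")
    x = pts - pts.mean(axis=0)
    spec = np.abs(np.fft.rfft(x, axis=0)) * (2.0 / n)
    spec[0] /= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def peak_frequency(traj, fs: float | None = None) -> float:
    """Frequency (Hz) of the dominant non-DC spectral component."""
    freqs, spec = amplitude_spectrum(traj, fs)
    power = spec[1:].sum(axis=1) if spec.ndim == 2 else spec[1:]
    return float(freqs[1 + int(np.argmax(power))])


def align_to_reference(traj, ref):
    """Shift a trajectory so its mean position equals the reference mean.

    Removes the constant spatial offset between tumor centroid and
    fiducial marker (they are different anatomical points), so grading
    compares motion patterns rather than absolute positions.
    """
    pts = _points(traj)
    ref_pts = _points(ref)
    if len(pts) != len(ref_pts):
        raise ValueError("trajectory and reference lengths differ")
    aligned = pts - pts.mean(axis=0) + ref_pts.mean(axis=0)
    if hasattr(traj, "points"):
        return replace(traj, points=aligned)
    return aligned


def rmse_grade(traj_aligned, ref) -> GradeReport:
    """Per-axis RMSE against the reference, final error E, and grade.

    E is the maximum of the two directional RMSEs; the grade bands are
    E < 3 px Excellent, 3-8 High, 8-13 Moderate, >= 13 Low.
    """
    pts = _points(traj_aligned)
    ref_pts = _points(ref)
    if pts.shape != ref_pts.shape:
        raise ValueError("trajectory and reference shapes differ")
    rmse = np.sqrt(np.mean((pts - ref_pts) ** 2, axis=0))
    e = float(rmse.max())
    return GradeReport(float(rmse[0]), float(rmse[1]), e, grade_for_error(e))


def trajectory_3d(
    traj_a: Trajectory2D,
    traj_b: Trajectory2D,
    geom_a: ProjectionGeometry,
    geom_b: ProjectionGeometry,
    residual_flag_mm: float = 2.0,
) -> Trajectory3D:
    """Frame-wise stereo triangulation of two synchronized 2-D trajectories.

    Each returned point is the closest-approach midpoint of the two
    back-projected rays; frames whose triangulation residual exceeds
    ``residual_flag_mm`` are flagged rather than rejected.
    """
    if len(traj_a) != len(traj_b):
        raise ValueError("stereo trajectories have different lengths")
    pts = np.empty((len(traj_a), 3))
    residuals = np.empty(len(traj_a))
    for k in range(len(traj_a)):
        pts[k], residuals[k] = triangulate(geom_a, traj_a.points[k], geom_b, traj_b.points[k])
    flags = residuals > residual_flag_mm
    return Trajectory3D(pts, fs=traj_a.fs, residuals=residuals, flags=flags)


@dataclass
class ErrorStats3D:
    """Per-axis absolute-error statistics (mm) and Euclidean summary."""

    mean_abs: np.ndarray  # (LR, SI, AP)
    sd_abs: np.ndarray
    euclidean: np.ndarray  # per frame
    median_euclidean: float
    iqr_euclidean: float


def error_stats_3d(traj: Trajectory3D, ref: Trajectory3D) -> ErrorStats3D:
    """Compare a 3-D trajectory with its reference frame by frame."""
    pts = _points(traj)
    ref_pts = _points(ref)
    if pts.shape != ref_pts.shape:
        raise ValueError("trajectory and reference shapes differ")
    delta = pts - ref_pts
    abs_err = np.abs(delta)
    eucl = np.linalg.norm(delta, axis=1)
    q1, q3 = np.percentile(eucl, [25, 75])
    return ErrorStats3D(
        mean_abs=abs_err.mean(axis=0),
        sd_abs=abs_err.std(axis=0),
        euclidean=eucl,
        median_euclidean=float(np.median(eucl)),
        iqr_euclidean=float(q3 - q1),
    )


def _quadratic_peak_offset(c_minus: float, c0: float, c_plus: float) -> float:
    denom = c_minus - 2.0 * c0 + c_plus
    if denom >= 0:  # not a local maximum; keep the integer peak
        return 0.0
    return float(np.clip(0.5 * (c_minus - c_plus) / denom, -0.5, 0.5))


def marker_track_template(
    stack: np.ndarray,
    template: np.ndarray,
    start: tuple[float, float],
    fs: float = 30.0,
    search_radius: int = 10,
    min_corr: float = 0.5,
) -> Trajectory2D:
    """Track a fiducial marker by normalized cross-correlation.

    Each frame is searched in a window of ``search_radius`` px around the
    previous position; the NCC peak is refined to sub-pixel precision by
    a separable quadratic fit.  Frames whose peak correlation falls below
    ``min_corr`` keep the previous position and are flagged.  This is a
    deliberately simple reference tracker for producing marker
    trajectories, not an optical-flow method.
    """
    from skimage.feature import match_template

    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, H, W)")
    template = np.asarray(template, dtype=np.float64)
    th, tw = template.shape
    n, h, w = stack.shape
    if th > h or tw > w:
        raise ValueError("template larger than frame")
    x0, y0 = float(start[0]), float(start[1])
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("start position outside frame")
    pts = np.empty((n, 2))
    flags = np.zeros(n, dtype=bool)
    pos = np.array([x0, y0])
    for k in range(n):
        cx, cy = int(round(pos[0])), int(round(pos[1]))
        half_w = tw // 2 + search_radius
        half_h = th // 2 + search_radius
        xa = max(cx - half_w, 0)
        ya = max(cy - half_h, 0)
        xb = min(cx + half_w + 1, w)
        yb = min(cy + half_h + 1, h)
        window = stack[k, ya:yb, xa:xb]
        if window.shape[0] < th or window.shape[1] < tw:
            flags[k] = True
            pts[k] = pos
            continue
        corr = match_template(window, template)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[iy, ix] < min_corr:
            flags[k] = True
            pts[k] = pos
            continue
        dx = dy = 0.0
        if 0 < ix < corr.shape[1] - 1:
            dx = _quadratic_peak_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
        if 0 < iy < corr.shape[0] - 1:
            dy = _quadratic_peak_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
        pos = np.array(
            [xa + ix + dx + (tw - 1) / 2.0, ya + iy + dy + (th - 1) / 2.0]
        )
        pts[k] = pos
    return Trajectory2D(pts, fs=fs, flags=flags)
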