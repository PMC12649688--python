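"""Empirical fluoroscopic noise characterization and device calibration.

Given a stack of frames of a *static* phantom, the temporal average is a
near-noise-free reference.  Subtracting it from each frame isolates the
noise, from which two per-pixel statistics are computed:

* noise probability ``P_N(x, y)``: the fraction of frames in which the
  absolute deviation from the average exceeds a threshold tau (default 2
  grayscale levels), and
* noise amplitude ``A_N(x, y)``: the mean absolute deviation.

Binning these maps by the average-image intensity yields the content
dependency curves; a weighted bright-region centroid estimates the beam
center; and a grid search over the spatial model
``B + (Max - B) * (1 - exp(-d^2 / (2 sigma_d^2)))`` calibrates the
spatial parameters.  Together these are the four calibration steps needed
to port the degradation model to a new imaging device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .content import ContentCurves

__all__ = [
    "average_frames",
    "noise_probability_map",
    "noise_amplitude_map",
    "intensity_curves",
    "fit_content_curve",
    "estimate_beam_center",
    "calibrate_spatial",
    "characterize_stack",
    "BinnedCurves",
    "BeamCenterEstimate",
    "SpatialCalibration",
    "CharacterizationResult",
]


def _as_stack(stack: np.ndarray) -> np.ndarray:
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("frame stack must be a (n_frames, H, W) array")
    return arr


def average_frames(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise temporal mean of a frame stack (the clean reference)."""
    arr = _as_stack(stack)
    if arr.shape[0] < 2:
        raise ValueError("averaging needs at least 2 frames")
    return arr.mean(axis=0)


def noise_probability_map(stack: np.ndarray, avg: np.ndarray, tau: float = 2.0) -> np.ndarray:
    """Fraction of frames with |frame - avg| > tau, per pixel."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    arr = _as_stack(stack)
    if arr.shape[1:] != np.shape(avg):
        raise ValueError("average image shape does not match the stack")
    return (np.abs(arr - avg) > tau).mean(axis=0)


def noise_amplitude_map(stack: np.ndarray, avg: np.ndarray) -> np.ndarray:
    """Mean absolute deviation from the average, per pixel."""
    arr = _as_stack(stack)
    if arr.shape[1:] != np.shape(avg):
        raise ValueError("average image shape does not match the stack")
    return np.abs(arr - avg).mean(axis=0)


class BinnedCurves(NamedTuple):
    """Per-intensity-bin (0..255) means of the noise maps; count 0 = empty bin."""

    pn: np.ndarray
    an: np.ndarray
    counts: np.ndarray


def intensity_curves(
    avg: np.ndarray, pn_map: np.ndarray, an_map: np.ndarray, sb_mask: np.ndarray
) -> BinnedCurves:
    """Intensity -> noise curves, restricted to the imaging field.

    Pixels are binned by their rounded average-image value (the clean
    content proxy); background pixels outside ``sb_mask`` never enter any
    bin.  Empty bins carry NaN means and a zero count.
    """
    avg = np.asarray(avg, dtype=np.float64)
    if not (avg.shape == np.shape(pn_map) == np.shape(an_map) == np.shape(sb_mask)):
        raise ValueError("maps and mask must share one shape")
    sel = np.asarray(sb_mask, dtype=bool)
    bins = np.clip(np.rint(avg[sel]).astype(np.int64), 0, 255)
    counts = np.bincount(bins, minlength=256)
    sum_pn = np.bincount(bins, weights=np.asarray(pn_map)[sel], minlength=256)
    sum_an = np.bincount(bins, weights=np.asarray(an_map)[sel], minlength=256)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pn = np.where(counts > 0, sum_pn / counts, np.nan)
        mean_an = np.where(counts > 0, sum_an / counts, np.nan)
    return BinnedCurves(mean_pn, mean_an, counts)


def fit_content_curve(
    bin_values: np.ndarray, degree: int = 10, smoothing_window: int = 9
) -> np.ndarray:
    """Least-squares polynomial fit to a smoothed intensity-noise curve.

    ``bin_values`` is a length-256 array with NaN at empty bins.  The
    populated part of the curve is smoothed with a centered moving average
    before fitting; returns ascending coefficients in u = V/255 (the
    :class:`~fluorotrack.content.ContentCurves` convention).
    """
    vals = np.asarray(bin_values, dtype=np.float64)
    if vals.shape != (256,):
        raise ValueError("expected one value per intensity bin (length 256)")
    populated = np.flatnonzero(np.isfinite(vals))
    if populated.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} populated bins to fit degree {degree}, "
            f"got {populated.size}"
        )
    y = vals[populated]
    kernel = np.ones(smoothing_window)
    smoothed = np.convolve(y, kernel, mode="same") / np.convolve(
        np.ones_like(y), kernel, mode="same"
    )
    design = np.vander(populated / 255.0, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, smoothed, rcond=None)
    return coeffs


class BeamCenterEstimate(NamedTuple):
    x: float
    y: float
    flat: bool  # True when the image carries no brightness structure


def estimate_beam_center(avg: np.ndarray, sb_mask: np.ndarray) -> BeamCenterEstimate:
    """Locate the X-ray beam axis from the brightness distribution.

    The beam axis shows up as the brightness peak of the average image, so
    the estimate is the intensity-weighted centroid of in-mask pixels at
    or above the 90th brightness percentile.  A perfectly flat image has
    no peak; the geometric image center is returned with ``flat`` set.
    """
    avg = np.asarray(avg, dtype=np.float64)
    sel = np.asarray(sb_mask, dtype=bool)
    if not sel.any():
        raise ValueError("SB mask selects no pixels")
    vals = avg[sel]
    h, w = avg.shape
    if vals.max() - vals.min() <= 0:
        return BeamCenterEstimate((w - 1) / 2.0, (h - 1) / 2.0, True)
    thr = np.percentile(vals, 90)
    yy, xx = np.nonzero(sel & (avg >= thr))
    wts = avg[yy, xx]
    return BeamCenterEstimate(
        float(np.average(xx, weights=wts)), float(np.average(yy, weights=wts)), False
    )


@dataclass
class SpatialCalibration:
    """Spatial-model parameters fitted to the observed noise maps."""

    sigma_d: float  # flatness radius from the probability map, px
    bp: float
    pmax: float
    sigma_a: float  # flatness radius from the amplitude map, px
    ba: float
    mmax: float
    prob_insensitive: bool
    amp_insensitive: bool
    sse_p: float
    sse_a: float


def _radial_profile(values: np.ndarray, beam_center, n_bins: int):
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - beam_center[0], yy - beam_center[1]).ravel()
    v = values.ravel()
    edges = np.linspace(0.0, d.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers[keep], sums[keep] / counts[keep]


def _fit_one_map(values, beam_center, sigma_grid, base_grid, n_bins, flat_tol):
    r, obs = _radial_profile(np.asarray(values, dtype=np.float64), beam_center, n_bins)
    spread = obs.max() - obs.min()
    if spread <= flat_tol * max(abs(obs.mean()), 1e-12):
        # e.g. newer-generation detectors: amplitude uniform over the field
        return float(np.max(sigma_grid)), float(obs.mean()), float(obs.mean()), True, 0.0
    best = None
    for sigma in sigma_grid:
        f = 1.0 - np.exp(-(r**2) / (2.0 * float(sigma) ** 2))
        ff = float(f @ f)
        for b in base_grid:
            resid = obs - float(b)
            amp = float(f @ resid) / ff if ff > 0 else 0.0
            amp = max(amp, 0.0)
            sse = float(np.sum((resid - amp * f) ** 2))
            if best is None or sse < best[0]:
                best = (sse, float(sigma), float(b), float(b) + amp)
    sse, sigma_hat, b_hat, max_hat = best
    return sigma_hat, b_hat, max_hat, False, sse


def calibrate_spatial(
    pn_map: np.ndarray,
    an_map: np.ndarray,
    beam_center,
    sigma_grid,
    base_grid_p,
    base_grid_a=None,
    n_bins: int = 64,
    flat_tol: float = 0.05,
) -> SpatialCalibration:
    """Grid-search the spatial parameters against observed noise maps.

    Each map is radially binned about the beam center and fitted with
    ``B + (Max - B) * (1 - exp(-d^2/(2 sigma_d^2)))``; for every
    (sigma_d, B) grid point the best Max is the linear least-squares
    solution, and the returned parameters minimize the binned
    sum-of-squares.  A map whose radial profile varies by less than
    ``flat_tol`` (relative) is flagged spatially insensitive and reported
    at the grid's largest sigma_d - the regime where the spatial factor is
    effectively constant over the field of view.
    """
    sigma_grid = np.asarray(sigma_grid, dtype=np.float64)
    base_grid_p = np.asarray(base_grid_p, dtype=np.float64)
    if sigma_grid.size == 0 or base_grid_p.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if base_grid_a is None:
        base_grid_a = base_grid_p
    base_grid_a = np.asarray(base_grid_a, dtype=np.float64)
    if base_grid_a.size == 0:
        raise ValueError("parameter grids must be non-empty")
    sp, bp, pmax, flat_p, sse_p = _fit_one_map(
        pn_map, beam_center, sigma_grid, base_grid_p, n_bins, flat_tol
    )
    sa, ba, mmax, flat_a, sse_a = _fit_one_map(
        an_map, beam_center, sigma_grid, base_grid_a, n_bins, flat_tol
    )
    return SpatialCalibration(sp, bp, pmax, sa, ba, mmax, flat_p, flat_a, sse_p, sse_a)


@dataclass
class CharacterizationResult:
    """Everything the degradation model needs, measured from one device."""

    avg_image: np.ndarray
    pn_map: np.ndarray
    an_map: np.ndarray
    tau: float
    curves: ContentCurves
    binned: BinnedCurves
    beam_center: BeamCenterEstimate
    spatial: SpatialCalibration
    noise_mean_hat: float

    def save(self, path: str, maps_prefix: str | None = None) -> None:
        """Scalars and polynomial coefficients as JSON; maps as float TIFF."""
        payload = {
            "tau": self.tau,
            "prob_coeffs": self.curves.prob_coeffs.tolist(),
            "amp_coeffs": self.curves.amp_coeffs.tolist(),
            "amp_factor": self.curves.amp_factor,
            "beam_center": [self.beam_center.x, self.beam_center.y],
            "beam_center_flat": self.beam_center.flat,
            "sigma_d": self.spatial.sigma_d,
            "bp": self.spatial.bp,
            "pmax": self.spatial.pmax,
            "sigma_a": self.spatial.sigma_a,
            "ba": self.spatial.ba,
            "mmax": self.spatial.mmax,
            "prob_insensitive": self.spatial.prob_insensitive,
            "amp_insensitive": self.spatial.amp_insensitive,
            "noise_mean_hat": self.noise_mean_hat,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        if maps_prefix is not None:
            import tifffile

            tifffile.imwrite(f"{maps_prefix}_avg.tif", self.avg_image.astype(np.float32))
            tifffile.imwrite(f"{maps_prefix}_pn.tif", self.pn_map.astype(np.float32))
            tifffile.imwrite(f"{maps_prefix}_an.tif", self.an_map.astype(np.float32))


def characterize_stack(
    stack: np.ndarray,
    sb_mask: np.ndarray | None = None,
    tau: float = 2.0,
    degree: int = 10,
    smoothing_window: int = 9,
    sigma_grid=None,
    base_grid_p=None,
    base_grid_a=None,
    beam_center: tuple[float, float] | None = None,
) -> CharacterizationResult:
    """Run the full calibration on a static-phantom frame stack.

    Steps: temporal average; P_N/A_N maps; intensity binning inside the
    SB mask; polynomial content fits; beam-center estimate; spatial-grid
    calibration.  Grids default to sigma_d in 60..200 px (step 4) and base
    levels spanning each observed map.
    """
    from .drr import standard_background_mask

    arr = _as_stack(stack)
    avg = average_frames(arr)
    if sb_mask is None:
        sb_mask = standard_background_mask((avg.shape[1], avg.shape[0]))
    pn = noise_probability_map(arr, avg, tau)
    an = noise_amplitude_map(arr, avg)
    binned = intensity_curves(avg, pn, an, sb_mask)
    curves = ContentCurves(
        prob_coeffs=fit_content_curve(binned.pn, degree, smoothing_window),
        amp_coeffs=fit_content_curve(binned.an, degree, smoothing_window),
        amp_factor=1.0,  # measured curves already carry the true amplitude scale
    )
    if beam_center is None:
        center = estimate_beam_center(avg, sb_mask)
    else:
        center = BeamCenterEstimate(float(beam_center[0]), float(beam_center[1]), False)
    if sigma_grid is None:
        sigma_grid = np.arange(60.0, 201.0, 4.0)
    if base_grid_p is None:
        base_grid_p = np.linspace(pn.min(), max(pn.mean(), pn.min() + 1e-6), 11)
    if base_grid_a is None:
        base_grid_a = np.linspace(an.min(), max(an.mean(), an.min() + 1e-6), 11)
    spatial = calibrate_spatial(pn, an, (center.x, center.y), sigma_grid, base_grid_p, base_grid_a)
    sel = np.asarray(sb_mask, dtype=bool)
    noise_mean_hat = float((arr - avg)[:, sel].mean())
    return CharacterizationResult(avg, pn, an, tau, curves, binned, center, spatial, noise_mean_hat)
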