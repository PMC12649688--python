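"""Stochastic content- and spatially-dependent image degradation.

Clean DRRs are degraded into fluoroscopy-like images in three stages:

1.  Per-pixel noise-characteristic maps.  Noise probability Np and
    amplitude Na are products of a content factor (polynomial in the clean
    pixel intensity V) and a spatial factor that grows with radial
    distance d from the X-ray beam center,

        f_s(d) = B + (1 - exp(-d^2 / (2 sigma_d^2))),

    linearly rescaled so the raw product spans [Bp, Pmax] (probability)
    and [Ba, Mmax] (amplitude).

2.  Sparse noise generation and diffusion.  A Bernoulli(Np) mask selects
    noisy pixels; Gaussian noise N(mu, Na(p)) is placed there, blurred
    with a sigma = 2.0 Gaussian (the scatter/detector diffusion), added to
    the clean image, and a fresh secondary draw at the same locations is
    added on top before clipping to 8 bits.

3.  Stochastic parameter resampling.  Beam-center offset, flatness radius
    and base levels are redrawn per generated image so a paired dataset
    spans a family of plausible devices and acquisition settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .content import ContentCurves, content_factor, default_content_curves

__all__ = [
    "DegradationParams",
    "NoiseMaps",
    "radial_distance_map",
    "spatial_factor",
    "scale_map",
    "build_noise_maps",
    "sample_degradation_params",
    "degrade",
    "build_paired_dataset",
]


@dataclass
class DegradationParams:
    """Every scalar the degradation draw depends on, plus its seed.

    Pmax/Mmax are device-level upper limits for noise probability and
    amplitude (0.92 and 16 grayscale levels from experimental
    observation); Bp/Ba are the base levels at the beam center; sigma_d is
    the central flatness radius in px; Xc the beam-center offset from the
    image geometric center in px.
    """

    Pmax: float = 0.92
    Mmax: float = 16.0
    Bp: float = 0.36
    Ba: float = 1.9
    sigma_d: float = 108.0
    Xc: tuple[float, float] = (0.0, 0.0)
    diffusion_sigma: float = 2.0
    noise_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.Bp <= self.Pmax <= 1.0):
            raise ValueError("need 0 <= Bp <= Pmax <= 1")
        if not (0.0 <= self.Ba <= self.Mmax):
            raise ValueError("need 0 <= Ba <= Mmax")
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be positive")
        if self.diffusion_sigma < 0:
            raise ValueError("diffusion_sigma must be non-negative")
        self.Xc = (float(self.Xc[0]), float(self.Xc[1]))


@dataclass
class NoiseMaps:
    """Per-pixel noise probability and amplitude maps (Np, Na)."""

    np_map: np.ndarray
    na_map: np.ndarray


def radial_distance_map(image_size: tuple[int, int], Xc=(0.0, 0.0)) -> np.ndarray:
    """Distance of each pixel from the beam center, in px.

    The beam center is the image geometric center ((W-1)/2, (H-1)/2)
    displaced by the offset ``Xc = (xc, yc)``.
    """
    w, h = int(image_size[0]), int(image_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("image size must be positive")
    cx = (w - 1) / 2.0 + float(Xc[0])
    cy = (h - 1) / 2.0 + float(Xc[1])
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - cx, yy - cy)


def spatial_factor(d, sigma_d: float, B: float):
    """Spatial dependency f_s(d) = B + (1 - exp(-d^2 / (2 sigma_d^2))).

    Noise is minimal (base level B) at the beam center and saturates at
    B + 1 far from it; sigma_d sets how wide the flat central region is.
    """
    if sigma_d <= 0:
        raise ValueError("sigma_d must be positive")
    d = np.asarray(d, dtype=np.float64)
    out = B + (1.0 - np.exp(-(d**2) / (2.0 * sigma_d**2)))
    return out if out.shape else float(out)


def scale_map(raw: np.ndarray, B: float, Max: float) -> np.ndarray:
    """Affine map of a raw characteristic to the target range [B, Max].

    The raw minimum maps to B and the raw maximum to Max; a constant raw
    map (no usable dynamic range) maps everywhere to the base level B.
    """
    if Max < B:
        raise ValueError("need Max >= B")
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.full_like(raw, B)
    return B + (raw - lo) * ((Max - B) / (hi - lo))


def build_noise_maps(
    clean: np.ndarray,
    params: DegradationParams,
    curves: ContentCurves | None = None,
) -> NoiseMaps:
    """Noise probability/amplitude maps for a clean image.

    Both maps are built from the *clean* intensities (the pre-degradation
    content V) and the radial distance map of the frame.
    """
    if curves is None:
        curves = default_content_curves()
    clean = np.asarray(clean, dtype=np.float64)
    if clean.ndim != 2:
        raise ValueError("clean image must be 2-D")
    h, w = clean.shape
    d = radial_distance_map((w, h), params.Xc)
    raw_p = content_factor(clean, curves, "prob") * spatial_factor(d, params.sigma_d, params.Bp)
    raw_a = content_factor(clean, curves, "amp") * spatial_factor(d, params.sigma_d, params.Ba)
    return NoiseMaps(
        np_map=scale_map(raw_p, params.Bp, params.Pmax),
        na_map=scale_map(raw_a, params.Ba, params.Mmax),
    )


def sample_degradation_params(seed, base: DegradationParams | None = None) -> DegradationParams:
    """Draw one stochastic parameter set for a degraded-image variant.

    Resampling ranges: each Xc component ~ N(0, 30 px); sigma_d ~
    U(103, 113) px; Bp ~ U(0.35, 0.37); Ba ~ U(1.8, 2.0).  Pmax, Mmax,
    diffusion sigma and the noise mean stay at their (or ``base``'s)
    fixed values.  The returned ``seed`` drives the subsequent noise draw
    and is itself derived from ``seed``, so one integer reproduces the
    whole variant.
    """
    if base is None:
        base = DegradationParams()
    rng = np.random.default_rng(seed)
    xc = rng.normal(0.0, 30.0, size=2)
    return replace(
        base,
        Xc=(float(xc[0]), float(xc[1])),
        sigma_d=float(rng.uniform(103.0, 113.0)),
        Bp=float(rng.uniform(0.35, 0.37)),
        Ba=float(rng.uniform(1.8, 2.0)),
        seed=int(rng.integers(0, 2**31)),
    )


def degrade(
    clean: np.ndarray,
    params: DegradationParams,
    curves: ContentCurves | None = None,
    maps: NoiseMaps | None = None,
    secondary: bool = True,
    clip: bool = True,
) -> np.ndarray:
    """Degrade one clean 8-bit-range frame.

    Fully determined by ``params.seed``.  RNG draw order is fixed: the
    uniform mask matrix R first, then primary noise values at masked
    pixels in row-major order, then secondary values.  ``secondary`` and
    ``clip`` can be disabled for exact statistical tests (closed-form
    noise laws assume a single Gaussian event per pixel and no clipping);
    setting ``params.diffusion_sigma = 0`` disables the diffusion blur.
    Precomputed ``maps`` may be passed when degrading many frames of the
    same clean image with identical parameters.
    """
    clean = np.asarray(clean, dtype=np.float64)
    if clean.min() < 0 or clean.max() > 255:
        raise ValueError("clean image must be in the 8-bit range [0, 255]")
    if maps is None:
        maps = build_noise_maps(clean, params, curves)
    rng = np.random.default_rng(params.seed)
    r = rng.random(clean.shape)
    mask = r < maps.np_map
    sigma = maps.na_map[mask]
    sparse = np.zeros_like(clean)
    sparse[mask] = rng.normal(params.noise_mean, sigma)
    if params.diffusion_sigma > 0:
        blurred = gaussian_filter(sparse, params.diffusion_sigma, mode="reflect", truncate=4.0)
    else:
        blurred = sparse
    out = clean + blurred
    if secondary:
        sec = np.zeros_like(clean)
        sec[mask] = rng.normal(params.noise_mean, sigma)
        out = out + sec
    if clip:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def build_paired_dataset(
    clean_dir,
    variants_per_image: int,
    master_seed: int,
    out_dir,
    curves: ContentCurves | None = None,
    base: DegradationParams | None = None,
):
    """Build a paired clean/degraded dataset for style-transfer training.

    Every clean image in ``clean_dir`` (PNG/TIFF, sorted by name) receives
    ``variants_per_image`` degraded copies, each with freshly resampled
    stochastic parameters.  Returns the manifest as a DataFrame, also
    written to ``out_dir/manifest.csv`` with one row per pair recording
    the drawn parameters.  Unreadable inputs are skipped with a warning.
    """
    import imageio.v3 as iio
    import pandas as pd

    clean_dir = Path(clean_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if curves is None:
        curves = default_content_curves()
    rows = []
    paths = sorted(p for p in clean_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
    for i, path in enumerate(paths):
        try:
            clean = np.asarray(iio.imread(path), dtype=np.float64)
        except Exception as exc:  # unreadable file: skip, keep going
            warnings.warn(f"skipping unreadable input {path}: {exc}", stacklevel=2)
            continue
        if clean.ndim == 3:
            clean = clean[..., 0]
        for j in range(variants_per_image):
            child = np.random.SeedSequence([master_seed, i, j])
            params = sample_degradation_params(child, base)
            deg = degrade(clean, params, curves)
            out_path = out_dir / f"{path.stem}_deg{j:03d}.png"
            iio.imwrite(out_path, deg)
            rows.append(
                {
                    "clean_path": str(path),
                    "degraded_path": str(out_path),
                    "seed": params.seed,
                    "Bp": params.Bp,
                    "Ba": params.Ba,
                    "sigma_d": params.sigma_d,
                    "Xc_x": params.Xc[0],
                    "Xc_y": params.Xc[1],
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
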