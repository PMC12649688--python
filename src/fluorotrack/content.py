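"""Content dependency of fluoroscopic noise on pixel intensity.

Empirically, noise probability and amplitude depend on the local grayscale
value in four phases: a rapid ascent at low intensities, a plateau over
the mid range, a sharp decline where clipping at the 255 grayscale ceiling
suppresses large excursions, and a partial recovery near full brightness.
Both dependencies are represented as 10th-order polynomials fitted to
smoothed measured curves.

Polynomial coefficients are stored in ascending powers of the *scaled*
intensity ``u = V / 255`` (so the domain is [0, 1]); fitting a degree-10
polynomial directly in V would be numerically hopeless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ContentCurves", "content_factor", "default_content_curves"]


@dataclass
class ContentCurves:
    """Degree-10 polynomial content curves f_vp (probability) and f_va (amplitude).

    ``amp_factor`` multiplies the evaluated amplitude curve; the default
    factor of 2 matches the empirically observed amplitude scale.
    """

    prob_coeffs: np.ndarray
    amp_coeffs: np.ndarray
    amp_factor: float = 2.0

    def __post_init__(self) -> None:
        self.prob_coeffs = np.asarray(self.prob_coeffs, dtype=np.float64)
        self.amp_coeffs = np.asarray(self.amp_coeffs, dtype=np.float64)

    def evaluate(self, intensity: np.ndarray, kind: str) -> np.ndarray:
        """Evaluate one curve at intensities in [0, 255], clipped at >= 0."""
        return content_factor(intensity, self, kind)


def _polyval_scaled(coeffs: np.ndarray, intensity: np.ndarray) -> np.ndarray:
    u = np.asarray(intensity, dtype=np.float64) / 255.0
    return np.polynomial.polynomial.polyval(u, coeffs)


def content_factor(intensity, curves: ContentCurves, kind: str):
    """Content-dependency factor f_vp(V) or f_va(V) for intensities V.

    Values are clipped at zero (a polynomial fit can dip negative near the
    domain edges); the amplitude curve is additionally multiplied by
    ``curves.amp_factor``.
    """
    v = np.asarray(intensity, dtype=np.float64)
    if np.any(v < 0) or np.any(v > 255):
        raise ValueError("intensity values must lie in [0, 255]")
    if kind == "prob":
        out = np.maximum(_polyval_scaled(curves.prob_coeffs, v), 0.0)
    elif kind == "amp":
        out = np.maximum(_polyval_scaled(curves.amp_coeffs, v), 0.0) * curves.amp_factor
    else:
        raise ValueError(f"unknown curve kind: {kind!r}")
    return out if out.shape else float(out)


# Control points (intensity, value) of the default four-phase curves:
# rapid ascent to the plateau at 85, plateau to 190 (probability ~0.81,
# amplitude ~6.5), sharp decline to 225, recovery over 225-255 averaging
# ~0.56 (probability) and ~2.75 (amplitude).
_PROB_KNOTS = ((0.0, 0.30), (85.0, 0.81), (190.0, 0.81), (225.0, 0.45), (255.0, 0.67))
_AMP_KNOTS = ((0.0, 1.00), (85.0, 6.50), (190.0, 6.50), (225.0, 1.50), (255.0, 4.00))


def _fit_default(knots, degree: int = 10, smoothing_window: int = 9) -> np.ndarray:
    v = np.arange(256, dtype=np.float64)
    kx, ky = zip(*knots)
    curve = np.interp(v, kx, ky)
    # centered moving average; edges use the shrinking window
    kernel = np.ones(smoothing_window)
    smoothed = np.convolve(curve, kernel, mode="same") / np.convolve(
        np.ones_like(curve), kernel, mode="same"
    )
    design = np.vander(v / 255.0, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(design, smoothed, rcond=None)
    return coeffs


def default_content_curves() -> ContentCurves:
    """Shipped default curves honoring the measured four-phase structure.

    Real deployments calibrate device-specific curves from static-phantom
    frame stacks; these defaults give the model a realistic shape out of
    the box.
    """
    return ContentCurves(
        prob_coeffs=_fit_default(_PROB_KNOTS),
        amp_coeffs=_fit_default(_AMP_KNOTS),
        amp_factor=2.0,
    )
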