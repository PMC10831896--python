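"""Difference-of-Gaussian spot detection.

Spots are detected per frame by filtering with the difference of two
Gaussian blurs — σ₁ = diameter/(2√2) expressed in pixels and σ₂ = √2·σ₁,
the standard blob-detector convention for a stated blob diameter — and
keeping local maxima of the filtered image whose response ("quality")
reaches an absolute threshold. The configuration mirrors the tracking
software used on the real movies: spot diameter 0.5 μm, quality cut 50.
Quality is defined as the DoG response at the peak; the synthetic movies
are calibrated so genuine spots score well above 50 and background maxima
well below, which is the role the threshold plays.

Sub-pixel positions come from 3×3 quadratic interpolation of the DoG peak
(adequate at the 0.4 μm linking gate); an optional Gaussian-fit refinement
is available. Coordinates are x = column·pixel_size, y = row·pixel_size,
with the origin at the center of pixel (0, 0) and 0-based frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

from .images import ImageStack

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "quality", "channel"]


@dataclass
class DetectionConfig:
    diameter: float = 0.5  # μm
    quality_threshold: float = 50.0
    pixel_size: float = 0.16  # μm/pixel
    channel: str = "ch0"
    refine: str = "quadratic"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.refine not in ("quadratic", "gaussian"):
            raise ValueError("refine must be 'quadratic' or 'gaussian'")

    @property
    def sigma1_px(self) -> float:
        return self.diameter / (2.0 * math.sqrt(2.0) * self.pixel_size)

    @property
    def sigma2_px(self) -> float:
        return math.sqrt(2.0) * self.sigma1_px


def dog_filter(frame_image: np.ndarray, diameter: float, pixel_size: float) -> np.ndarray:
    """Difference of two Gaussian blurs tuned to the spot diameter."""
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    s1 = diameter / (2.0 * math.sqrt(2.0) * pixel_size)
    if s1 < 0.5:
        raise ValueError("diameter spans less than one pixel")
    if min(img.shape) < int(4 * s1) + 1:
        raise ValueError("image smaller than the filter support")
    return gaussian_filter(img, s1) - gaussian_filter(img, math.sqrt(2.0) * s1)


def _quadratic_offset(fm1: float, f0: float, fp1: float) -> float:
    """Vertex of the parabola through (-1, fm1), (0, f0), (1, fp1)."""
    denom = fm1 - 2.0 * f0 + fp1
    if denom >= 0:  # not a maximum; keep the integer peak
        return 0.0
    off = 0.5 * (fm1 - fp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def _gaussian_refine(img: np.ndarray, row: int, col: int, sigma_px: float) -> tuple[float, float]:
    """Least-squares 2-D Gaussian fit on a patch around the integer peak."""
    h = max(3, int(math.ceil(2 * sigma_px)))
    r0, r1 = max(row - h, 0), min(row + h + 1, img.shape[0])
    c0, c1 = max(col - h, 0), min(col + h + 1, img.shape[1])
    patch = img[r0:r1, c0:c1].astype(float)
    rr, cc = np.mgrid[r0:r1, c0:c1]

    def resid(p):
        amp, x0, y0, s, bg = p
        return (amp * np.exp(-((cc - x0) ** 2 + (rr - y0) ** 2) / (2 * s**2)) + bg - patch).ravel()

    p0 = [patch.max() - patch.min(), col, row, sigma_px, patch.min()]
    sol = least_squares(resid, p0, max_nfev=200)
    return float(sol.x[1]), float(sol.x[2])


def detect_spots(stack: ImageStack, config: DetectionConfig) -> pd.DataFrame:
    """Detect spots in every frame of a stack.

    Per frame: DoG filter, local maxima with minimum separation equal to the
    spot diameter, quality = DoG value at the maximum, sub-pixel refinement,
    threshold at ``quality_threshold``. Returns a detection table with
    columns frame, x_um, y_um, quality, channel (positions in μm).
    """
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    min_sep = max(1, int(round(config.diameter / config.pixel_size)))
    rows = []
    for f in range(stack.n_frames):
        dog = dog_filter(stack.data[f], config.diameter, config.pixel_size)
        peaks = peak_local_max(
            dog,
            min_distance=min_sep,
            threshold_abs=config.quality_threshold,
            exclude_border=1,
        )
        for r, c in peaks:
            quality = dog[r, c]
            if config.refine == "gaussian":
                x_px, y_px = _gaussian_refine(dog, r, c, config.sigma1_px)
            else:
                x_px = c + _quadratic_offset(dog[r, c - 1], dog[r, c], dog[r, c + 1])
                y_px = r + _quadratic_offset(dog[r - 1, c], dog[r, c], dog[r + 1, c])
            rows.append((f, x_px * config.pixel_size, y_px * config.pixel_size, quality))
    df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "quality"])
    df["channel"] = config.channel
    return df[DETECTION_COLUMNS]


def write_detections(path, detections: pd.DataFrame) -> None:
    detections.to_csv(path, index=False, float_format="%.6f")


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path)
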