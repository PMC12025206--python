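"""Sample-inlet (flat region) extraction from measurement-cell photographs.

A backlit measurement cell photographed through a phone camera shows a flat,
uniformly colored liquid inlet surrounded by textured housing.  The inlet is
located as the square window with the lowest second-derivative (Laplacian)
magnitude: the image is converted to grayscale, filtered with the 8-direction
Laplacian kernel, and a fixed-size window is slid over the gradient map; the
window with the smallest aggregate gradient is returned together with its
R, G, B channel arrays, which feed the RGBscore computation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

#: BT.601 luma weights -- the default grayscale conversion of mainstream
#: imaging libraries.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: 3x3 second-derivative kernel responding to texture in all eight neighbor
#: directions (center -8, all neighbors +1; zero-sum, so constants map to 0).
LAPLACIAN_8 = np.array(
    [[1.0, 1.0, 1.0],
     [1.0, -8.0, 1.0],
     [1.0, 1.0, 1.0]]
)


@dataclass(frozen=True)
class RoiSelection:
    """The chosen window of a photograph plus its per-channel arrays.

    ``gradient_intensity`` is the window-aggregate Laplacian magnitude used
    to rank candidate windows (mean by default); recomputing the statistic
    on the gradient map reproduces it exactly.
    """

    origin_row: int
    origin_col: int
    size: int
    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    gradient_intensity: float

    @property
    def channel_means(self) -> tuple[float, float, float]:
        return (float(self.R.mean()), float(self.G.mean()), float(self.B.mean()))

    def to_report(self) -> dict:
        mr, mg, mb = self.channel_means
        return {
            "origin_row": int(self.origin_row),
            "origin_col": int(self.origin_col),
            "size": int(self.size),
            "gradient_intensity": float(self.gradient_intensity),
            "mean_r": mr,
            "mean_g": mg,
            "mean_b": mb,
        }

    def save_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2) + "\n")


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/JPEG into an H x W x 3 uint8 array.

    Alpha channels are stripped with a logged warning; grayscale inputs are
    broadcast to three identical channels.
    """
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA"):
            logger.warning("image %s has an alpha channel; stripping it", path)
            im = im.convert("RGB")
        elif im.mode != "RGB":
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    return arr


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError(f"expected a nonempty HxWx3 RGB image, got shape {image.shape}")
    return image


def to_grayscale(image: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS) -> np.ndarray:
    """Weighted-luma grayscale conversion (BT.601 by default).

    gray = wr*R + wg*G + wb*B per pixel, returned as float64.
    """
    image = _validate_rgb(image)
    wr, wg, wb = weights
    img = image.astype(np.float64)
    return wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]


def laplacian_gradient(gray: np.ndarray) -> np.ndarray:
    """Absolute response of the 8-direction Laplacian, replicate-edge padded.

    Both positive and negative curvature count as texture, so the magnitude
    is taken per pixel; a constant (or affine) image maps to zero in the
    interior.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or min(gray.shape) < 3:
        raise ValueError(f"gradient filtering needs a 2-D image of at least 3x3, got shape {gray.shape}")
    response = ndimage.convolve(gray, LAPLACIAN_8, mode="nearest")
    return np.abs(response)


def _origins(extent: int, window: int, stride: int) -> list[int]:
    """Window origins along one axis: every multiple of ``stride`` with the
    window inside the image, end-clamped so the far edge is always covered."""
    last = extent - window
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def window_gradient(grad: np.ndarray, row: int, col: int, size: int, statistic: str = "mean") -> float:
    """The scan statistic of one window, computed directly on the slice."""
    block = grad[row : row + size, col : col + size]
    if statistic == "mean":
        return float(block.mean())
    if statistic == "sum":
        return float(block.sum())
    raise ValueError(f"unknown window statistic {statistic!r}")


def scan_windows(
    grad: np.ndarray,
    window: int,
    stride: int = 10,
    statistic: str = "mean",
) -> list[tuple[int, int, float]]:
    """Slide a square window over a gradient map, upper-left to bottom-right.

    Returns ``(origin_row, origin_col, gradient_intensity)`` for every
    visited origin in row-major order.  Origins step by ``stride`` and the
    maximal origin along each axis is appended when the stride does not land
    on it exactly, so the bottom-right corner is always covered.

    Window sums are evaluated through a summed-area table, which makes the
    scan cost independent of the window size.
    """
    grad = np.asarray(grad, dtype=np.float64)
    if grad.ndim != 2:
        raise ValueError("gradient map must be 2-D")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = grad.shape
    if window < 1 or window > h or window > w:
        raise ValueError(f"window {window} does not fit a {h}x{w} gradient map")
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown window statistic {statistic!r}")

    rows = np.array(_origins(h, window, stride))
    cols = np.array(_origins(w, window, stride))
    sat = np.zeros((h + 1, w + 1))
    sat[1:, 1:] = grad.cumsum(axis=0).cumsum(axis=1)
    r0 = rows[:, None]
    c0 = cols[None, :]
    sums = (
        sat[r0 + window, c0 + window]
        - sat[r0, c0 + window]
        - sat[r0 + window, c0]
        + sat[r0, c0]
    )
    stats = sums / (window * window) if statistic == "mean" else sums
    return [
        (int(r), int(c), float(stats[i, j]))
        for i, r in enumerate(rows)
        for j, c in enumerate(cols)
    ]


def extract_roi(
    image: np.ndarray,
    window: int = 200,
    stride: int = 10,
    statistic: str = "mean",
    gray_weights: tuple[float, float, float] = BT601_WEIGHTS,
) -> RoiSelection:
    """Locate the flattest window of a photograph and return its channels.

    Ties on the minimum gradient are broken by the first occurrence in
    row-major scan order. The channel arrays are copied from the original
    color image at the winning window; ``gradient_intensity`` is recomputed
    directly on the gradient-map slice so it is reproducible bit-for-bit.
    """
    image = _validate_rgb(image)
    gray = to_grayscale(image, gray_weights)
    grad = laplacian_gradient(gray)
    candidates = scan_windows(grad, window, stride, statistic)
    stats = np.array([s for (_, _, s) in candidates])
    best = int(np.argmin(stats))  # argmin returns the first minimum: row-major tie-break
    row, col, _ = candidates[best]
    img = image.astype(np.float64)
    return RoiSelection(
        origin_row=row,
        origin_col=col,
        size=window,
        R=img[row : row + window, col : col + window, 0].copy(),
        G=img[row : row + window, col : col + window, 1].copy(),
        B=img[row : row + window, col : col + window, 2].copy(),
        gradient_intensity=window_gradient(grad, row, col, window, statistic),
    )
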