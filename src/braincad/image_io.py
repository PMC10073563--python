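"""Grayscale image and binary-mask I/O plus intensity histograms.

Raster conventions used throughout the package:

* images are 2-D :class:`numpy.ndarray` with origin at the top-left corner,
  coordinates ``(row, column)``, 0-based;
* integer-mode images are ``uint8`` with intensities in ``[0, 255]``;
  enhanced images are real-valued ``float64`` until re-quantized;
* binary masks are ``uint8`` arrays of ``{0, 1}`` in memory and are stored
  on disk as 8-bit rasters with foreground ``255``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "IntensityHistogram",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
    "to_histogram",
]

# ITU-R BT.601 luminance weights for RGB inputs.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class IntensityHistogram:
    """256-bin intensity histogram of an 8-bit image.

    Attributes
    ----------
    counts
        ``counts[k]`` is the number of pixels with intensity ``k``.
    probabilities
        ``counts / counts.sum()``; sums to one.
    """

    counts: np.ndarray
    probabilities: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _validate_integer_image(image: np.ndarray, what: str = "image") -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{what} must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(
            f"{what} must be integer-mode (quantize enhanced images first), got dtype {arr.dtype}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"{what} intensities must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image; RGB inputs are converted to luminance.

    Returns a ``uint8`` array of shape ``(height, width)``.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image {path} is zero-sized")
    if raw.ndim == 3:
        # drop an alpha channel if present, then BT.601 luminance, round half-up
        rgb = raw[..., :3].astype(np.float64)
        gray = np.floor(rgb @ _BT601 + 0.5)
        raw = np.clip(gray, 0, 255)
    elif raw.ndim != 2:
        raise ValueError(f"image {path} has unsupported shape {raw.shape}")
    return raw.astype(np.uint8)


def write_gray_image(image: np.ndarray, path: str | Path) -> None:
    """Write an integer-mode image as an 8-bit PNG/TIFF raster."""
    arr = _validate_integer_image(image)
    try:
        iio.imwrite(Path(path), arr)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot write image {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 raster as a {0,1} binary mask."""
    arr = read_gray_image(path)
    return (arr > 127).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit raster with foreground 255."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    write_gray_image((arr * 255).astype(np.uint8), path)


def to_histogram(image: np.ndarray) -> IntensityHistogram:
    """256-bin histogram and per-level probabilities of an integer-mode image."""
    arr = _validate_integer_image(image)
    counts = np.bincount(arr.ravel(), minlength=256).astype(np.int64)
    probabilities = counts / counts.sum()
    return IntensityHistogram(counts=counts, probabilities=probabilities)
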