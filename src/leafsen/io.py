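"""Image and mask I/O.

Images are plain numpy arrays of shape (H, W, C), dtype float64, values in
[0, 1], channel order R, G, B. Masks are boolean arrays of shape (H, W).
Quantization happens only at file boundaries; every algorithmic stage works
on floats.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "as_image",
    "as_mask",
]


def as_image(arr: np.ndarray) -> np.ndarray:
    """Validate and canonicalize an array as an (H, W, C) float image in [0, 1]."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[:, :, np.newaxis]
    if a.ndim != 3:
        raise ValueError(f"image must be 2-D or 3-D, got shape {arr.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1 or a.shape[2] < 1:
        raise ValueError(f"image has empty dimension: shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("image contains non-finite values")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValueError(
            f"image values must lie in [0, 1], got range [{a.min():g}, {a.max():g}]"
        )
    return a


def as_mask(arr: np.ndarray, like: np.ndarray | None = None) -> np.ndarray:
    """Validate a boolean (H, W) mask, optionally against a reference image."""
    m = np.asarray(arr)
    if m.dtype != bool:
        m = m.astype(bool)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if like is not None and m.shape != like.shape[:2]:
        raise ValueError(
            f"mask shape {m.shape} does not match image shape {like.shape[:2]}"
        )
    return m


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or TIFF into a float image in [0, 1].

    8-bit data is divided by 255, 16-bit by 65535. An alpha channel is
    dropped; grayscale files yield a single-channel (H, W, 1) image.
    """
    raw = iio.imread(path)
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(
            f"unsupported bit depth {raw.dtype} in {path!s}; expected uint8 or uint16"
        )
    a = raw.astype(np.float64) / scale
    if a.ndim == 3 and a.shape[2] in (2, 4):  # drop alpha (gray+A or RGBA)
        a = a[:, :, : a.shape[2] - 1]
    return as_image(a)


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Clip to [0, 1], quantize to 8 bits and write as PNG.

    Round-trip error through load_image is bounded by 1/255 per pixel
    per channel.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim == 3 and a.shape[2] == 1:
        a = a[:, :, 0]
    q = np.clip(np.rint(np.clip(a, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(os.fspath(path), q, extension=".png")


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean mask."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return raw > 127


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    m = as_mask(mask)
    iio.imwrite(os.fspath(path), (m.astype(np.uint8) * 255), extension=".png")
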