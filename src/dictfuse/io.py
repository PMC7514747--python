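"""Grayscale image I/O.

A *GrayImage* throughout this package is a 2-D ``float64`` numpy array with
intensities on ``[0, 1]``.  Files are read and written through :mod:`imageio`
(PNG and TIFF); 8- and 16-bit integer rasters are rescaled by their dtype
maximum on load and quantized to 8 bits on save.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image", "as_gray_image"]

# ITU-R BT.601 luminance weights, used only under luminance=True.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray_image(arr: np.ndarray, *, luminance: bool = False) -> np.ndarray:
    """Coerce an array decoded from a file to a [0, 1] float64 grayscale image.

    Integer dtypes are divided by their maximum representable value; float
    inputs are assumed to already be on [0, 1].  A trailing RGB(A) axis is
    collapsed by BT.601 luminance only when ``luminance`` is set, otherwise a
    multi-channel input is an error.
    """
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        img = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        img = arr.astype(np.float64)
    if img.ndim == 3:
        if not luminance:
            raise ValueError(
                "multi-channel image; pass luminance=True to convert to grayscale"
            )
        if img.shape[2] not in (3, 4):
            raise ValueError(f"unsupported channel count {img.shape[2]}")
        img = img[..., :3] @ _LUMA
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixel values")
    return img


def load_image(path: str | Path, *, luminance: bool = False) -> np.ndarray:
    """Load a PNG/TIFF raster as a [0, 1] grayscale image.

    Parameters
    ----------
    path : path-like
        Single-channel PNG or TIFF file (8- or 16-bit, or float).
    luminance : bool
        Convert RGB(A) input to grayscale by BT.601 luminance.  Without this
        flag a multi-channel file raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise OSError(f"could not read image {path}: {exc}") from exc
    return as_gray_image(raw, luminance=luminance)


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as an 8-bit PNG/TIFF.

    Values are clipped to [0, 1] before quantization, so
    ``load_image(save_image(x))`` agrees with ``clip(x, 0, 1)`` to within
    half an 8-bit quantization step (max abs error <= 1/255).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    quantized = np.clip(np.round(np.clip(img, 0.0, 1.0) * 255.0), 0, 255)
    iio.imwrite(Path(path), quantized.astype(np.uint8))
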