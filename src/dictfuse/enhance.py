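"""Multi-level detail enhancement of dictionary-training images.

Weakly contrasted structures in a source image are poorly represented when
patches are harvested from it directly.  Before training, each image is
therefore enriched with its own high-frequency content: a neighbour-distance
(ND) highpass residual is extracted at several smoothing levels and the
residuals are added back onto the image.  Enhancement is applied *only* to
the dictionary-training inputs — the images being fused are never enhanced.

All neighbourhood operations use reflective (symmetric) border padding.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["neighbor_distance_filter", "enhance_details"]


def _mean_filter(img: np.ndarray, window: int) -> np.ndarray:
    return ndimage.uniform_filter(img, size=window, mode="reflect")


def neighbor_distance_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Neighbour-distance highpass: the image minus its windowed mean.

    ``ND(X) = X - mean_{w x w}(X)`` with symmetric border handling, so the
    residual is exactly zero wherever the image is locally constant and has
    (machine-precision) zero mean over the whole frame.

    Parameters
    ----------
    img : 2-D array
    window : odd int >= 3
        Side of the averaging neighbourhood.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("neighbor-distance window must be odd and >= 3")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return img - _mean_filter(img, window)


def enhance_details(img: np.ndarray, levels: int = 4, window: int = 3) -> np.ndarray:
    """Add ``levels`` neighbour-distance detail layers onto an image.

    Detail layers are taken from a progressively smoothed sequence
    ``S_0 = X``, ``S_p = mean(S_{p-1})`` as ``H_p = ND(S_{p-1})``, capturing
    detail from fine to coarse, and the enhanced image is
    ``X + sum_p H_p``.  The output is intentionally not clipped: clipping
    happens only when an image is finally saved.

    Parameters
    ----------
    img : 2-D array
    levels : int >= 1
        Number of detail layers ``P``.
    window : odd int >= 3
        ND / smoothing window side.
    """
    if levels < 1:
        raise ValueError("number of enhancement levels must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    out = img.copy()
    smooth = img
    for _ in range(levels):
        out += neighbor_distance_filter(smooth, window)
        smooth = _mean_filter(smooth, window)
    return out
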