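"""Multi-scale sampling and sliding-window patch handling.

Training images are decimated at several rates (keep every ``d``-th pixel
starting from the first, so a dimension ``N`` becomes ``ceil(N / d)``) and
each scale is cut into overlapping square patches by a sliding window that
moves in steps of ``delta`` pixels from the upper left to the lower right.
Patches stop at the last full window, so each axis yields
``floor((dim - rho) / delta) + 1`` patches.  On a 256x256 image with
``rho = 8`` and ``delta = 2`` this gives 15625 patches at full scale and
3721 / 1600 / 841 / 529 at rates 2 / 3 / 4 / 5 (6691 in total).

Vectorization is column-stacked (Fortran order) and every patch carries its
provenance: source image, decimation rate, grid index, and top-left corner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "PatchSet",
    "downsample",
    "extract_patches",
    "reconstruct_from_patches",
    "patch_grid_shape",
]


def downsample(img: np.ndarray, d: int) -> np.ndarray:
    """Decimate an image by rate ``d``: keep every d-th pixel from the first.

    No anti-alias prefilter is applied; the goal is patch diversity, not
    signal fidelity.  Output dimensions are ``ceil(H/d) x ceil(W/d)``.
    """
    if d < 1:
        raise ValueError("downsampling rate must be >= 1")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    return img[::d, ::d].copy()


def patch_grid_shape(shape: tuple[int, int], patch_size: int, step: int) -> tuple[int, int]:
    """Patch counts per axis: ``floor((dim - rho) / delta) + 1``."""
    h, w = shape
    if h < patch_size or w < patch_size:
        raise ValueError(
            f"image {shape} smaller than patch size {patch_size}; no patches"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    return ((h - patch_size) // step + 1, (w - patch_size) // step + 1)


@dataclass
class PatchSet:
    """Vectorized patches of one image plus their provenance.

    Attributes
    ----------
    vectors : (rho^2, K) array
        Column-stacked (Fortran-order) patch vectors, one column per patch.
    rows, cols : (K,) int arrays
        Top-left corner of each patch in the image it came from.
    patch_size, step : int
        Window side ``rho`` and sliding step ``delta``.
    image_shape : (int, int)
        Shape of the image the patches were extracted from.
    source : int
        Index of the source image (``l``).
    rate : int
        Decimation rate of the image (``d``; 1 means unsampled).
    """

    vectors: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    patch_size: int
    step: int
    image_shape: tuple[int, int]
    source: int = 0
    rate: int = 1

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return patch_grid_shape(self.image_shape, self.patch_size, self.step)

    def provenance(self) -> list[tuple[int, int, int]]:
        """(source, rate, grid index) triple per patch, in column order."""
        return [(self.source, self.rate, k) for k in range(self.n_patches)]

    def patch(self, k: int) -> np.ndarray:
        """The k-th patch as a 2-D array."""
        rho = self.patch_size
        return self.vectors[:, k].reshape(rho, rho, order="F")


def extract_patches(
    img: np.ndarray,
    patch_size: int,
    step: int,
    *,
    source: int = 0,
    rate: int = 1,
) -> PatchSet:
    """Cut an image into overlapping ``rho x rho`` patches.

    The window slides row-major from the upper-left corner in ``step``-pixel
    increments, stopping at the last offset where a full window fits.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    n_r, n_c = patch_grid_shape(img.shape, patch_size, step)
    windows = sliding_window_view(img, (patch_size, patch_size))[::step, ::step]
    # column-stacked vectorization: patch.flatten(order="F") per window
    vectors = (
        windows.transpose(0, 1, 3, 2)
        .reshape(n_r * n_c, patch_size * patch_size)
        .T.copy()
    )
    rows = np.repeat(np.arange(n_r) * step, n_c)
    cols = np.tile(np.arange(n_c) * step, n_r)
    return PatchSet(
        vectors=vectors,
        rows=rows,
        cols=cols,
        patch_size=patch_size,
        step=step,
        image_shape=img.shape,
        source=source,
        rate=rate,
    )


def reconstruct_from_patches(
    patches: PatchSet, out_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Fold patches back into an image, averaging overlapping pixels.

    Values and visit counts are accumulated per pixel and divided.  When the
    step does not divide ``dim - rho`` a strip at the right/bottom border is
    never covered by any window; those pixels are filled from their nearest
    covered pixel and a warning is emitted.
    """
    if out_shape is None:
        out_shape = patches.image_shape
    rho = patches.patch_size
    if any(s < rho for s in out_shape):
        raise ValueError("output shape smaller than the patch size")
    accum = np.zeros(out_shape, dtype=np.float64)
    count = np.zeros(out_shape, dtype=np.float64)
    for k in range(patches.n_patches):
        r, c = patches.rows[k], patches.cols[k]
        if r + rho > out_shape[0] or c + rho > out_shape[1]:
            raise ValueError(f"patch {k} at ({r},{c}) falls outside {out_shape}")
        accum[r : r + rho, c : c + rho] += patches.patch(k)
        count[r : r + rho, c : c + rho] += 1.0
    uncovered = count == 0
    if np.any(uncovered):
        warnings.warn(
            f"{int(uncovered.sum())} pixels not covered by any patch; "
            "filled from nearest covered pixel",
            stacklevel=2,
        )
        out = np.where(uncovered, 0.0, accum / np.where(uncovered, 1.0, count))
        _, (ir, ic) = ndimage.distance_transform_edt(
            uncovered, return_indices=True
        )
        return np.where(uncovered, out[ir, ic], out)
    return accum / count
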