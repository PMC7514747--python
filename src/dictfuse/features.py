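"""Brightness and detail activity statistics.

Two per-pixel maps drive patch clustering:

* **SNE** (sum of neighbourhood energy): the windowed sum of squared
  intensities, a brightness/energy measure.
* **MSF** (multi-scale spatial frequency): spatial-frequency maps — windowed
  sums of absolute central differences — are computed at three neighbourhood
  scales and combined as a weighted sum of absolute between-scale
  differences, a detail measure robust to the choice of a single window.

Per-patch features are footprint sums of these maps (``E`` for brightness,
``C`` for detail).  All neighbourhood sums use reflective (symmetric)
padding, consistent with the enhancement stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .sampling import PatchSet

__all__ = ["FeatureTable", "sne_map", "sf_map", "msf_map", "patch_features"]


def _check_odd(value: int, name: str) -> None:
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{name} must be an odd positive integer, got {value}")


def sne_map(img: np.ndarray, window: int = 11) -> np.ndarray:
    """Sum of squared intensities over an ``M x M`` window, per pixel."""
    _check_odd(window, "SNE window")
    img = np.asarray(img, dtype=np.float64)
    return ndimage.uniform_filter(img * img, size=window, mode="reflect") * (
        window * window
    )


def sf_map(img: np.ndarray, r: int, mode: str = "abs") -> np.ndarray:
    """Single-scale spatial frequency: windowed central-difference activity.

    ``SP_r(i, j) = sum_{(m, n) in r x r window} g(X(i+m, j+n) - X(i, j))``
    with ``g = |.|`` by default.  ``mode="square"`` squares the differences;
    ``mode="raw"`` keeps them signed (the raw form largely telescopes and is
    retained only for comparison).
    """
    _check_odd(r, "SF scale")
    if mode not in ("abs", "square", "raw"):
        raise ValueError("mode must be 'abs', 'square' or 'raw'")
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    pad = (r - 1) // 2
    padded = np.pad(img, pad, mode="symmetric")
    out = np.zeros_like(img)
    for m in range(r):
        for n in range(r):
            diff = padded[m : m + h, n : n + w] - img
            if mode == "abs":
                out += np.abs(diff)
            elif mode == "square":
                out += diff * diff
            else:
                out += diff
    return out


def msf_map(
    img: np.ndarray,
    scales: tuple[int, int, int] = (7, 11, 15),
    weights: tuple[float, float] = (0.33, 0.67),
    mode: str = "abs",
) -> np.ndarray:
    """Multi-scale spatial frequency map.

    ``MSF = w1 * |SP_r1 - SP_r2| + w2 * |SP_r1 - SP_r3|`` pointwise, with
    ``r1 < r2 < r3``.  Non-negative by construction.
    """
    r1, r2, r3 = scales
    if not r1 < r2 < r3:
        raise ValueError(f"scales must be strictly increasing, got {scales}")
    w1, w2 = weights
    if w1 < 0 or w2 < 0:
        raise ValueError("weights must be non-negative")
    sp1 = sf_map(img, r1, mode)
    sp2 = sf_map(img, r2, mode)
    sp3 = sf_map(img, r3, mode)
    return w1 * np.abs(sp1 - sp2) + w2 * np.abs(sp1 - sp3)


@dataclass
class FeatureTable:
    """Per-patch brightness (``E``) and detail (``C``) sums, aligned to the
    columns of the :class:`~dictfuse.sampling.PatchSet` they were computed
    from."""

    energy: np.ndarray
    detail: np.ndarray

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=np.float64)
        self.detail = np.asarray(self.detail, dtype=np.float64)
        if self.energy.shape != self.detail.shape or self.energy.ndim != 1:
            raise ValueError("energy and detail must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.energy.size


def _footprint_sums(map2d: np.ndarray, patches: PatchSet) -> np.ndarray:
    """Sum of a per-pixel map over each patch footprint (integral image)."""
    rho = patches.patch_size
    integral = np.zeros((map2d.shape[0] + 1, map2d.shape[1] + 1))
    integral[1:, 1:] = map2d.cumsum(axis=0).cumsum(axis=1)
    r, c = patches.rows, patches.cols
    return (
        integral[r + rho, c + rho]
        - integral[r, c + rho]
        - integral[r + rho, c]
        + integral[r, c]
    )


def patch_features(
    patches: PatchSet, sne: np.ndarray, msf: np.ndarray
) -> FeatureTable:
    """Aggregate SNE and MSF maps into per-patch E and C features.

    The maps must have been computed on the same grid the patches were
    extracted from.
    """
    sne = np.asarray(sne, dtype=np.float64)
    msf = np.asarray(msf, dtype=np.float64)
    if sne.shape != patches.image_shape or msf.shape != patches.image_shape:
        raise ValueError(
            f"feature maps {sne.shape}/{msf.shape} do not match the patch "
            f"grid image shape {patches.image_shape}"
        )
    return FeatureTable(
        energy=_footprint_sums(sne, patches),
        detail=_footprint_sums(msf, patches),
    )
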