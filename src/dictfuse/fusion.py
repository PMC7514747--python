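"""Sparse-representation image fusion.

Registered source images are cut into overlapping patches (no enhancement,
no multi-scale sampling at this stage — those belong to the learning branch
only), each patch is sparse-coded over the learned dictionary by OMP, the
per-patch codes compete under the max-absolute choosing rule, and the
winning codes are decoded and folded back with overlap averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import FusionConfig
from .dictionary import Dictionary, omp_encode_batch
from .sampling import PatchSet, extract_patches, reconstruct_from_patches

__all__ = ["SparseCodeSet", "select_fused_code", "fuse"]


@dataclass
class SparseCodeSet:
    """Per-source and fused sparse codes for one fusion run.

    Attributes
    ----------
    codes : (L, m, K) array
        OMP coefficients of every patch of every source.
    fused : (m, K) array
        The selected (fused) code per patch.
    selected : (K,) int array
        Which source each fused code came from (``-1`` when the elementwise
        blending rule is used and the fused code is not a single source's).
    patch_size, step : int
        Patch geometry of the fusion-stage grid.
    image_shape : (int, int)
        Shape of the source images.
    """

    codes: np.ndarray
    fused: np.ndarray
    selected: np.ndarray
    patch_size: int
    step: int
    image_shape: tuple[int, int]


def select_fused_code(codes: Sequence[np.ndarray]) -> np.ndarray:
    """Max-absolute choosing rule: the candidate with the largest l1 norm.

    Ties break deterministically toward the lowest source index.  This is a
    selection, not a blend: the result is one of the inputs.
    """
    if len(codes) == 0:
        raise ValueError("no candidate codes")
    stacked = np.stack([np.asarray(c, dtype=np.float64) for c in codes])
    activity = np.abs(stacked).sum(axis=1)
    return stacked[int(np.argmax(activity))].copy()


def fuse(
    images: Sequence[np.ndarray],
    dictionary: Dictionary,
    cfg: FusionConfig | None = None,
    *,
    return_codes: bool = False,
):
    """Fuse registered grayscale images with a learned dictionary.

    Parameters
    ----------
    images : sequence of 2-D arrays
        Two or more co-registered [0, 1] images of identical dimensions.
    dictionary : Dictionary
        Learned atom matrix; its atom dimension must equal
        ``cfg.patch_size ** 2``.
    cfg : FusionConfig, optional
        Patch geometry and OMP parameters; defaults are used when omitted.
    return_codes : bool
        Also return the :class:`SparseCodeSet` bookkeeping.

    Returns
    -------
    fused : 2-D array in [0, 1]
        Overlap-averaged reconstruction of the winning patch codes.
    """
    cfg = cfg or FusionConfig()
    if len(images) < 2:
        raise ValueError("fusion requires at least two source images")
    arrays = [np.asarray(img, dtype=np.float64) for img in images]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"source dimensions differ: {sorted(shapes)}")
    if dictionary.atom_dim != cfg.patch_dim:
        raise ValueError(
            f"dictionary atom dimension {dictionary.atom_dim} does not match "
            f"patch size {cfg.patch_size}^2 = {cfg.patch_dim}"
        )

    patch_sets = [
        extract_patches(a, cfg.patch_size, cfg.step, source=l)
        for l, a in enumerate(arrays)
    ]
    codes = np.stack(
        [
            omp_encode_batch(
                ps.vectors, dictionary.atoms, cfg.omp_tolerance, cfg.max_atoms
            )
            for ps in patch_sets
        ]
    )  # (L, m, K)

    if cfg.fusion_rule == "max_l1":
        activity = np.abs(codes).sum(axis=1)  # (L, K)
        selected = activity.argmax(axis=0)  # first max wins ties
        fused_codes = np.take_along_axis(
            codes, selected[None, None, :], axis=0
        )[0]
    else:  # elementwise max-absolute blending
        flat_winner = np.abs(codes).argmax(axis=0)  # (m, K)
        fused_codes = np.take_along_axis(codes, flat_winner[None], axis=0)[0]
        selected = np.full(codes.shape[2], -1, dtype=np.intp)

    template = patch_sets[0]
    fused_patches = PatchSet(
        vectors=dictionary.atoms @ fused_codes,
        rows=template.rows,
        cols=template.cols,
        patch_size=cfg.patch_size,
        step=cfg.step,
        image_shape=template.image_shape,
    )
    fused = np.clip(reconstruct_from_patches(fused_patches), 0.0, 1.0)
    if return_codes:
        return fused, SparseCodeSet(
            codes=codes,
            fused=fused_codes,
            selected=np.asarray(selected, dtype=np.intp),
            patch_size=cfg.patch_size,
            step=cfg.step,
            image_shape=template.image_shape,
        )
    return fused
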