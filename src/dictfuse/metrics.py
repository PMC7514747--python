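"""No-reference fusion quality metrics.

Medical fusion has no ground truth, so quality is judged against the source
images: mutual information (how much intensity information of each source
survives in the fused image, summed over sources) and the Xydeas-Petrovic
gradient-preservation measure Q^AB/F (how much edge strength and orientation
is transferred).  Larger is better for both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "pairwise_mutual_information",
    "mutual_information",
    "qabf",
    "evaluate",
]

# Xydeas-Petrovic sigmoid constants (edge strength / orientation).
_GAMMA_G, _KAPPA_G, _SIGMA_G = 0.9994, -15.0, 0.5
_GAMMA_A, _KAPPA_A, _SIGMA_A = 0.9879, -22.0, 0.8


def _quantize(img: np.ndarray, bins: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    return np.clip(np.round(img * (bins - 1)), 0, bins - 1).astype(np.intp)


def pairwise_mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int = 256
) -> float:
    """Mutual information I(X; Y) in bits from a joint ``bins``-level
    histogram of the 8-bit-quantized intensities."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"image dimensions differ: {x.shape} vs {y.shape}")
    joint = np.zeros((bins, bins))
    np.add.at(joint, (_quantize(x, bins), _quantize(y, bins)), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(
        np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask]))
    )


def mutual_information(
    fused: np.ndarray, a: np.ndarray, b: np.ndarray, bins: int = 256
) -> float:
    """Fusion MI: ``I(A; F) + I(B; F)`` in bits (256-level histograms)."""
    return pairwise_mutual_information(a, fused, bins) + pairwise_mutual_information(
        b, fused, bins
    )


def _sobel_edges(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient magnitude and orientation (atan of gy/gx, gx==0 -> pi/2)."""
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        ang = np.arctan(np.divide(gy, gx))
    ang = np.where(gx == 0, np.pi / 2, ang)
    return mag, ang


def _edge_preservation(
    g_src: np.ndarray, a_src: np.ndarray, g_f: np.ndarray, a_f: np.ndarray
) -> np.ndarray:
    """Per-pixel Q^{XF}: sigmoid-weighted strength and orientation transfer."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(g_src > g_f, g_f / g_src, g_src / g_f)
    ratio = np.where(np.maximum(g_src, g_f) == 0, 0.0, ratio)
    align = 1.0 - np.abs(a_src - a_f) / (np.pi / 2)
    q_g = _GAMMA_G / (1.0 + np.exp(_KAPPA_G * (ratio - _SIGMA_G)))
    q_a = _GAMMA_A / (1.0 + np.exp(_KAPPA_A * (align - _SIGMA_A)))
    return q_g * q_a


def qabf(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Xydeas-Petrovic edge-information-transfer measure Q^AB/F in [0, 1].

    Per-pixel preservation factors for each source are weighted by that
    source's Sobel edge strength and normalized by the total edge strength.
    Two flat sources score 0 by convention.
    """
    fused, a, b = (np.asarray(x, dtype=np.float64) for x in (fused, a, b))
    if not (fused.shape == a.shape == b.shape):
        raise ValueError("image dimensions differ")
    g_a, ang_a = _sobel_edges(a)
    g_b, ang_b = _sobel_edges(b)
    g_f, ang_f = _sobel_edges(fused)
    q_af = _edge_preservation(g_a, ang_a, g_f, ang_f)
    q_bf = _edge_preservation(g_b, ang_b, g_f, ang_f)
    denom = (g_a + g_b).sum()
    if denom == 0:
        return 0.0
    return float((q_af * g_a + q_bf * g_b).sum() / denom)


@dataclass
class MetricReport:
    """MI and Q^AB/F of one fused result against its two sources."""

    mi: float
    qabf: float

    def to_dict(self) -> dict:
        return {"mi": self.mi, "qabf": self.qabf}


def evaluate(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> MetricReport:
    """Compute the full metric report for a fused image."""
    return MetricReport(mi=mutual_information(fused, a, b), qabf=qabf(fused, a, b))
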