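"""Synthetic co-registered phantom pairs.

Real multimodal pairs (MRI/CT, MR-T1/MR-T2, ...) contrast a modality that is
bright and smooth where the other is dark but finely structured.  The
phantom generator emulates exactly that complementarity: image A carries
smooth Gaussian brightness blobs (energy-dominant content, placed on a
jittered grid so coverage is stable across seeds), image B carries
sinusoidal gratings and sharp bars (detail-dominant content), and a
noise-free composite reference carries both — giving synthetic experiments
the ground truth the clinical task lacks.  Both observed images are
degraded by modality noise; each source therefore covers only part of the
reference, which is what a successful fusion must recover.  Pairs are
pixel-aligned by construction and deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomSpec", "make_pair"]


@dataclass
class PhantomSpec:
    """Parameters of one phantom pair.

    Attributes
    ----------
    size : (int, int)
        Image dimensions.
    n_blobs : int
        Smooth Gaussian brightness blobs placed in image A.
    blob_intensity : float
        Upper bound of blob amplitudes.
    n_textures : int
        Textured rectangles (gratings) placed in image B.
    noise_sigma : float
        Std of additive Gaussian noise on A and B (the reference stays
        noise-free).
    seed : int
        Drives all randomness; identical seeds give identical pairs.
    """

    size: tuple[int, int] = (256, 256)
    n_blobs: int = 6
    blob_intensity: float = 0.9
    n_textures: int = 7
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 16 or w < 16:
            raise ValueError("phantom must be at least 16x16")
        if self.n_blobs < 1 or self.n_textures < 1:
            raise ValueError("need at least one blob and one texture")
        if not 0 < self.blob_intensity <= 1:
            raise ValueError("blob_intensity must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_pair(spec: PhantomSpec | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one co-registered phantom pair plus its composite reference.

    Returns
    -------
    (a, b, reference) : three 2-D [0, 1] arrays
        ``a`` is the brightness-dominant source (higher mean intensity),
        ``b`` the detail-dominant source (higher mean gradient magnitude),
        and ``reference`` the noise-free composite (pixelwise max of the two
        content layers) that a perfect fusion would recover.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # --- brightness source: soft ramp plus smooth bright blobs ----------
    base_a = 0.15 + 0.05 * xx / w
    blobs = np.zeros((h, w))
    scale = min(h, w)
    # jittered-grid placement keeps blob coverage stable across seeds
    cells = [(r, c) for r in range(3) for c in range(3)]
    rng.shuffle(cells)
    for i in range(spec.n_blobs):
        gr, gc = cells[i % len(cells)]
        cy = (gr + rng.uniform(0.25, 0.75)) / 3.0 * h
        cx = (gc + rng.uniform(0.25, 0.75)) / 3.0 * w
        sigma = rng.uniform(0.05, 0.09) * scale
        amp = rng.uniform(0.55, 1.0) * spec.blob_intensity
        blobs = np.maximum(
            blobs, amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        )
    content_a = np.clip(base_a + blobs, 0.0, 1.0)

    # --- detail source: dark background with textured rectangles --------
    content_b = np.full((h, w), 0.06)
    for _ in range(spec.n_textures):
        bh = int(rng.uniform(0.25, 0.45) * h)
        bw = int(rng.uniform(0.25, 0.45) * w)
        r0 = rng.integers(0, h - bh)
        c0 = rng.integers(0, w - bw)
        theta = rng.uniform(0.0, np.pi)
        period = rng.uniform(4.0, 10.0)  # pixels per cycle: sharp texture
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.30, 0.50)
        coord = xx * np.cos(theta) + yy * np.sin(theta)
        grating = 0.5 * (1.0 + np.sin(2 * np.pi * coord / period + phase))
        region = content_b[r0 : r0 + bh, c0 : c0 + bw]
        content_b[r0 : r0 + bh, c0 : c0 + bw] = np.maximum(
            region, 0.08 + amp * grating[r0 : r0 + bh, c0 : c0 + bw]
        )
    # a few sharp step edges (thin bright bars)
    for _ in range(2):
        r0 = rng.integers(h // 8, 7 * h // 8)
        c0 = rng.integers(0, w // 2)
        length = rng.integers(w // 4, w // 2)
        content_b[r0 : r0 + 2, c0 : c0 + length] = 0.85

    reference = np.maximum(content_a, content_b)

    a = content_a + rng.normal(0.0, spec.noise_sigma, (h, w))
    b = content_b + rng.normal(0.0, spec.noise_sigma, (h, w))
    return np.clip(a, 0.0, 1.0), np.clip(b, 0.0, 1.0), reference
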