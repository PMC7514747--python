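"""Pipeline configuration.

All intensity-dependent tolerances (notably the OMP reconstruction error)
are defined on the internal working scale, where images live in ``[0, 1]``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["FusionConfig"]


@dataclass
class FusionConfig:
    """Parameters of the dictionary-learning fusion pipeline.

    Defaults reproduce the reference operating point: 8x8 patches with
    6-pixel overlap (step 2), 4 enhancement levels, multi-scale sampling at
    rates 3/4/5/6, an 11x11 neighbourhood-energy window, spatial-frequency
    scales 7/11/15 weighted 0.33/0.67, two 128-atom sub-dictionaries trained
    by 50 K-SVD iterations with OMP reconstruction error 0.1.

    Parameters
    ----------
    patch_size : int
        Side length (pixels) of the square patches, ``rho``.
    overlap : int
        Overlapping pixels between adjacent patches; the sliding step is
        ``patch_size - overlap``.
    enhance_levels : int
        Number of neighbour-distance detail levels added during training-set
        enhancement, ``P``.
    nd_window : int
        Odd window of the neighbour-distance (mean-subtraction) filter.
    downsample_rates : sequence of int
        Decimation rates used by multi-scale sampling of the enhanced
        training images.
    sne_window : int
        Odd side of the sum-of-neighbourhood-energy window.
    msf_scales : (int, int, int)
        Odd, strictly increasing neighbourhood sides of the three
        spatial-frequency maps entering the multi-scale spatial frequency.
    msf_weights : (float, float)
        Non-negative weights of the two scale-difference terms.
    sf_mode : {"abs", "square", "raw"}
        How central differences are aggregated in the spatial-frequency map.
    atoms_per_subdict : int
        Atoms in each of the brightness and detail sub-dictionaries.
    ksvd_iterations : int
        K-SVD alternations.
    omp_tolerance : float
        Residual l2 norm at which OMP stops, on the [0, 1] intensity scale.
    max_atoms : int
        Hard cap on the OMP support size.
    fusion_rule : {"max_l1", "elementwise"}
        Per-patch coefficient fusion: select the whole code with the largest
        l1 activity (default), or take the elementwise max-absolute
        coefficient across sources.
    rng_seed : int
        Seed for every stochastic step (K-SVD initialization, phantoms).
    """

    patch_size: int = 8
    overlap: int = 6
    enhance_levels: int = 4
    nd_window: int = 3
    downsample_rates: tuple[int, ...] = (3, 4, 5, 6)
    sne_window: int = 11
    msf_scales: tuple[int, int, int] = (7, 11, 15)
    msf_weights: tuple[float, float] = (0.33, 0.67)
    sf_mode: str = "abs"
    atoms_per_subdict: int = 128
    ksvd_iterations: int = 50
    omp_tolerance: float = 0.1
    max_atoms: int = 16
    fusion_rule: str = "max_l1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.downsample_rates = tuple(int(d) for d in self.downsample_rates)
        self.msf_scales = tuple(int(r) for r in self.msf_scales)
        self.msf_weights = tuple(float(w) for w in self.msf_weights)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if not 0 <= self.overlap < self.patch_size:
            raise ValueError("overlap must satisfy 0 <= overlap < patch_size")
        if self.enhance_levels < 1:
            raise ValueError("enhance_levels must be >= 1")
        if self.nd_window < 3 or self.nd_window % 2 == 0:
            raise ValueError("nd_window must be odd and >= 3")
        if any(d < 1 for d in self.downsample_rates):
            raise ValueError("downsample rates must be >= 1")
        if self.sne_window < 1 or self.sne_window % 2 == 0:
            raise ValueError("sne_window must be odd and positive")
        r1, r2, r3 = self.msf_scales
        if not (r1 < r2 < r3):
            raise ValueError("msf_scales must be strictly increasing")
        if any(r % 2 == 0 or r < 1 for r in self.msf_scales):
            raise ValueError("msf_scales must be odd and positive")
        if any(w < 0 for w in self.msf_weights):
            raise ValueError("msf_weights must be non-negative")
        if self.sf_mode not in ("abs", "square", "raw"):
            raise ValueError("sf_mode must be 'abs', 'square' or 'raw'")
        if self.atoms_per_subdict < 1:
            raise ValueError("atoms_per_subdict must be positive")
        if self.ksvd_iterations < 1:
            raise ValueError("ksvd_iterations must be >= 1")
        if self.omp_tolerance <= 0:
            raise ValueError("omp_tolerance must be > 0")
        if self.max_atoms < 1:
            raise ValueError("max_atoms must be >= 1")
        if self.fusion_rule not in ("max_l1", "elementwise"):
            raise ValueError("fusion_rule must be 'max_l1' or 'elementwise'")

    # -- derived quantities ----------------------------------------------

    @property
    def step(self) -> int:
        """Sliding-window step ``delta = patch_size - overlap``."""
        return self.patch_size - self.overlap

    @property
    def patch_dim(self) -> int:
        """Length of a vectorized patch, ``patch_size ** 2``."""
        return self.patch_size * self.patch_size

    # -- (de)serialization -----------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FusionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FusionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config fields")
        # YAML has no tuple type; lists are accepted for tuple fields.
        return cls.from_dict(data)
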