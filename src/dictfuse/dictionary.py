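"""Competitive training sets, OMP sparse coding and K-SVD dictionary learning.

The dictionary is built from two competitively selected training sets: for
every patch-grid slot (scale ``d``, grid index ``k``) the source image whose
patch has the largest brightness feature ``E`` contributes that patch to the
brightness set, and the source with the largest detail feature ``C``
contributes to the detail set.  A patch is never allowed to sit in both sets
(exclusivity constraint): when one patch wins both contests it goes to the
set where its standardized feature is larger and the other set takes the
runner-up for that slot.  Each set trains one K-SVD sub-dictionary; the two
blocks are concatenated into the final overcomplete dictionary
``D = (D_brightness, D_detail)``.

Patch means are deliberately *not* removed before training or coding: the
brightness block is meant to carry energy, which mean removal would destroy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import FusionConfig
from .enhance import enhance_details
from .features import FeatureTable, msf_map, patch_features, sne_map
from .sampling import PatchSet, downsample, extract_patches

__all__ = [
    "TrainingSets",
    "Dictionary",
    "build_training_sets",
    "omp_encode",
    "omp_encode_batch",
    "ksvd_learn",
    "assemble_dictionary",
    "collect_training_patches",
    "learn_fusion_dictionary",
]

_NORM_TOL = 1e-9


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------


@dataclass
class TrainingSets:
    """Brightness-dominant and detail-dominant patch matrices.

    ``provenance`` entries are ``(source, rate, grid_index)`` triples aligned
    to the matrix columns; by construction the two provenance sets are
    disjoint.
    """

    brightness: np.ndarray
    detail: np.ndarray
    brightness_provenance: list[tuple[int, int, int]] = field(default_factory=list)
    detail_provenance: list[tuple[int, int, int]] = field(default_factory=list)


def build_training_sets(
    patch_sets: Sequence[PatchSet],
    feature_tables: Sequence[FeatureTable],
) -> TrainingSets:
    """Run the per-slot brightness/detail competitions across source images.

    Parameters
    ----------
    patch_sets, feature_tables
        Aligned sequences covering every (source, rate) combination; all
        sources must be present at every rate with identical patch grids.

    Notes
    -----
    Ties across sources go to the lowest source index.  When a single patch
    wins both contests it is assigned to the set where its z-scored feature
    (standardized over all patches of all sources and rates) is larger; the
    other set takes the runner-up for that slot, or omits the slot if there
    is no other candidate (single-source degenerate case).
    """
    if len(patch_sets) != len(feature_tables):
        raise ValueError("patch_sets and feature_tables must align")
    for ps, ft in zip(patch_sets, feature_tables):
        if ps.n_patches != len(ft):
            raise ValueError(
                f"feature table length {len(ft)} does not match patch count "
                f"{ps.n_patches} for source {ps.source}, rate {ps.rate}"
            )

    sources = sorted({ps.source for ps in patch_sets})
    if len(sources) < 2:
        warnings.warn(
            "single source image: competition is degenerate, winners are "
            "trivially the only candidates",
            stacklevel=2,
        )

    # z-scores over the entire patch population, used only for tie-breaking
    all_e = np.concatenate([ft.energy for ft in feature_tables])
    all_c = np.concatenate([ft.detail for ft in feature_tables])

    def _z(x: float, pop: np.ndarray) -> float:
        sd = pop.std()
        return 0.0 if sd == 0 else (x - pop.mean()) / sd

    by_rate: dict[int, list[tuple[PatchSet, FeatureTable]]] = {}
    for ps, ft in zip(patch_sets, feature_tables):
        by_rate.setdefault(ps.rate, []).append((ps, ft))

    bright_cols: list[np.ndarray] = []
    detail_cols: list[np.ndarray] = []
    bright_prov: list[tuple[int, int, int]] = []
    detail_prov: list[tuple[int, int, int]] = []

    for rate in sorted(by_rate):
        group = sorted(by_rate[rate], key=lambda pair: pair[0].source)
        counts = {ps.n_patches for ps, _ in group}
        if len(counts) != 1:
            raise ValueError(f"patch grids disagree across sources at rate {rate}")
        if {ps.source for ps, _ in group} != set(sources):
            raise ValueError(f"missing sources at rate {rate}")
        n_slots = counts.pop()
        e_mat = np.stack([ft.energy for _, ft in group])  # (L, K)
        c_mat = np.stack([ft.detail for _, ft in group])
        e_winner = e_mat.argmax(axis=0)  # first max wins ties (lowest l)
        c_winner = c_mat.argmax(axis=0)
        for k in range(n_slots):
            be, bc = int(e_winner[k]), int(c_winner[k])
            if be == bc and len(group) > 1:
                # one patch won both contests: keep it where its
                # standardized feature is larger, runner-up fills the other
                ze = _z(e_mat[be, k], all_e)
                zc = _z(c_mat[bc, k], all_c)
                order_e = np.argsort(-e_mat[:, k], kind="stable")
                order_c = np.argsort(-c_mat[:, k], kind="stable")
                if ze >= zc:
                    bc = int(order_c[order_c != bc][0])
                else:
                    be = int(order_e[order_e != be][0])
            if be == bc:  # single source: keep the brighter claim only
                ze = _z(e_mat[be, k], all_e)
                zc = _z(c_mat[bc, k], all_c)
                ps = group[be][0]
                if ze >= zc:
                    bright_cols.append(ps.vectors[:, k])
                    bright_prov.append((ps.source, rate, k))
                else:
                    detail_cols.append(ps.vectors[:, k])
                    detail_prov.append((ps.source, rate, k))
                continue
            ps_b = group[be][0]
            ps_c = group[bc][0]
            bright_cols.append(ps_b.vectors[:, k])
            bright_prov.append((ps_b.source, rate, k))
            detail_cols.append(ps_c.vectors[:, k])
            detail_prov.append((ps_c.source, rate, k))

    dim = patch_sets[0].vectors.shape[0]
    bright = np.column_stack(bright_cols) if bright_cols else np.empty((dim, 0))
    det = np.column_stack(detail_cols) if detail_cols else np.empty((dim, 0))
    return TrainingSets(
        brightness=bright,
        detail=det,
        brightness_provenance=bright_prov,
        detail_provenance=detail_prov,
    )


# ---------------------------------------------------------------------------
# dictionary container
# ---------------------------------------------------------------------------


@dataclass
class Dictionary:
    """Column-normalized atom matrix split into brightness and detail blocks.

    ``atoms`` has shape ``(n, m)`` with ``n`` the patch dimension and
    ``m > n`` (overcomplete); columns ``[0, n_brightness)`` form the
    brightness block, the rest the detail block.
    """

    atoms: np.ndarray
    n_brightness: int
    patch_size: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        if not 0 <= self.n_brightness <= self.atoms.shape[1]:
            raise ValueError("invalid brightness/detail partition")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(np.abs(norms - 1.0) > _NORM_TOL):
            raise ValueError("every atom must have unit l2 norm")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def atom_dim(self) -> int:
        return self.atoms.shape[0]

    @property
    def brightness_block(self) -> np.ndarray:
        return self.atoms[:, : self.n_brightness]

    @property
    def detail_block(self) -> np.ndarray:
        return self.atoms[:, self.n_brightness :]

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to an ``.npz`` archive with JSON metadata."""
        np.savez(
            Path(path),
            atoms=self.atoms,
            n_brightness=np.array(self.n_brightness),
            patch_size=np.array(-1 if self.patch_size is None else self.patch_size),
            meta=np.array(json.dumps(self.meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        with np.load(Path(path)) as data:
            patch_size = int(data["patch_size"])
            return cls(
                atoms=data["atoms"],
                n_brightness=int(data["n_brightness"]),
                patch_size=None if patch_size < 0 else patch_size,
                meta=json.loads(str(data["meta"])),
            )


def assemble_dictionary(
    brightness_atoms: np.ndarray,
    detail_atoms: np.ndarray,
    patch_size: int | None = None,
    meta: dict | None = None,
) -> Dictionary:
    """Concatenate the two sub-dictionary blocks, recording the partition."""
    brightness_atoms = np.asarray(brightness_atoms, dtype=np.float64)
    detail_atoms = np.asarray(detail_atoms, dtype=np.float64)
    if brightness_atoms.shape[0] != detail_atoms.shape[0]:
        raise ValueError(
            f"atom dimensions differ: {brightness_atoms.shape[0]} vs "
            f"{detail_atoms.shape[0]}"
        )
    return Dictionary(
        atoms=np.hstack([brightness_atoms, detail_atoms]),
        n_brightness=brightness_atoms.shape[1],
        patch_size=patch_size,
        meta=meta or {},
    )


# ---------------------------------------------------------------------------
# orthogonal matching pursuit
# ---------------------------------------------------------------------------


def omp_encode_batch(
    signals: np.ndarray,
    atoms: np.ndarray,
    tol: float,
    max_atoms: int,
) -> np.ndarray:
    """Error-constrained OMP codes for every column of ``signals``.

    Greedy selection by maximal absolute residual correlation with a full
    least-squares re-fit over the selected set at every step; a column's
    pursuit stops as soon as its residual l2 norm drops to ``tol`` or its
    support reaches ``max_atoms``.  Uses the precomputed Gram matrix, so the
    residual never needs to be formed explicitly.

    Returns a dense ``(m, K)`` coefficient matrix.
    """
    if tol <= 0:
        raise ValueError("tolerance must be > 0")
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    signals = np.asarray(signals, dtype=np.float64)
    if signals.ndim != 2:
        raise ValueError("signals must be a (n, K) matrix")
    n, m = atoms.shape
    if signals.shape[0] != n:
        raise ValueError(f"signal dim {signals.shape[0]} != atom dim {n}")
    max_atoms = min(max_atoms, m, n)

    gram = atoms.T @ atoms
    proj = atoms.T @ signals  # (m, K)
    sq_norms = np.einsum("ij,ij->j", signals, signals)
    tol_sq = tol * tol

    codes = np.zeros((m, K := signals.shape[1]))
    for k in range(K):
        resid_sq = sq_norms[k]
        if resid_sq <= tol_sq:
            continue
        dty = proj[:, k]
        corr = dty.copy()
        support: list[int] = []
        coef = np.empty(0)
        while resid_sq > tol_sq and len(support) < max_atoms:
            j = int(np.argmax(np.abs(corr)))
            if j in support or abs(corr[j]) < 1e-14:
                break  # numerical stall: nothing left to explain
            support.append(j)
            sub = np.ix_(support, support)
            try:
                coef = np.linalg.solve(gram[sub], dty[support])
            except np.linalg.LinAlgError:
                coef, *_ = np.linalg.lstsq(gram[sub], dty[support], rcond=None)
            corr = dty - gram[:, support] @ coef
            resid_sq = max(sq_norms[k] - coef @ dty[support], 0.0)
        codes[support, k] = coef
    return codes


def omp_encode(
    y: np.ndarray,
    dictionary: "Dictionary | np.ndarray",
    tol: float = 0.1,
    max_atoms: int = 16,
) -> np.ndarray:
    """OMP code of a single signal; see :func:`omp_encode_batch`."""
    atoms = dictionary.atoms if isinstance(dictionary, Dictionary) else dictionary
    y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    return omp_encode_batch(y, atoms, tol, max_atoms)[:, 0]


# ---------------------------------------------------------------------------
# K-SVD
# ---------------------------------------------------------------------------


def ksvd_learn(
    training: np.ndarray,
    n_atoms: int,
    iterations: int = 50,
    tol: float = 0.1,
    seed: int = 0,
    max_atoms: int = 16,
    min_usage: int = 4,
    coherence_limit: float = 0.99,
    return_info: bool = False,
):
    """Learn a unit-norm atom block from training vectors by K-SVD.

    Alternates error-constrained OMP coding of all training columns with
    sequential rank-1 SVD updates of each (atom, coefficient-row) pair over
    the atom's support.  Two stabilizers are applied:

    * **Monotone coding guard** — a column keeps its previous iteration's
      code whenever that code (which stays consistent with the updated
      dictionary) beats the freshly pursued one, so the Frobenius objective
      never increases across iterations that perform no atom replacement.
    * **Atom cleanup** — after each update sweep, atoms used by fewer than
      ``min_usage`` columns or nearly duplicating another atom (absolute
      inner product above ``coherence_limit``) are restarted on the
      currently worst-represented training column (renormalized).

    Parameters
    ----------
    training : (n, N) array
        Training vectors as columns, ``N >= n_atoms``.
    n_atoms : int
        Number of atoms to learn.
    iterations : int
        Number of code/update alternations.
    tol, max_atoms
        OMP stopping parameters used during coding.
    seed : int
        Seeds the initial atom draw; the whole run is deterministic given
        the seed.
    min_usage : int
        Minimum number of columns that must use an atom for it to survive
        cleanup (1 disables everything but dead-atom replacement).
    coherence_limit : float
        Duplicate-atom threshold on absolute mutual coherence.
    return_info : bool
        Also return a dict with the per-iteration Frobenius ``objective``
        trace (measured after each update sweep and cleanup) and
        per-iteration ``replacements`` counts.

    Returns
    -------
    atoms : (n, n_atoms) array, or ``(atoms, info)`` when ``return_info``.
    """
    training = np.asarray(training, dtype=np.float64)
    if training.ndim != 2:
        raise ValueError("training must be a (n, N) matrix")
    n, n_train = training.shape
    if n_train < n_atoms:
        raise ValueError(
            f"need at least {n_atoms} training columns, got {n_train}"
        )
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    col_norms = np.linalg.norm(training, axis=0)
    usable = np.flatnonzero(col_norms > 1e-12)
    if usable.size == 0:
        raise ValueError("training set is identically zero")
    if usable.size < n_atoms:
        raise ValueError(
            f"only {usable.size} non-zero training columns for {n_atoms} atoms"
        )

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(usable, size=n_atoms, replace=False)
    atoms = training[:, init_idx] / col_norms[init_idx]

    objective: list[float] = []
    replacements: list[int] = []
    prev_codes: np.ndarray | None = None

    for _ in range(iterations):
        codes = omp_encode_batch(training, atoms, tol, max_atoms)
        if prev_codes is not None:
            # monotone guard: keep last iteration's code where it is better
            new_res = np.linalg.norm(training - atoms @ codes, axis=0)
            old_res = np.linalg.norm(training - atoms @ prev_codes, axis=0)
            keep = old_res < new_res - 1e-12
            codes[:, keep] = prev_codes[:, keep]

        residual = training - atoms @ codes
        for j in range(n_atoms):
            support = np.flatnonzero(codes[j])
            if support.size == 0:
                continue  # handled by cleanup below
            err = residual[:, support] + np.outer(atoms[:, j], codes[j, support])
            u, s, vt = np.linalg.svd(err, full_matrices=False)
            new_atom = u[:, 0]
            if new_atom[np.argmax(np.abs(new_atom))] < 0:  # fix SVD sign
                new_atom = -new_atom
                s_row = -s[0] * vt[0]
            else:
                s_row = s[0] * vt[0]
            atoms[:, j] = new_atom
            codes[j, support] = s_row
            residual[:, support] = err - np.outer(new_atom, s_row)

        # cleanup: restart under-used or duplicate atoms
        col_err = np.einsum("ij,ij->j", residual, residual)
        gram_abs = np.abs(atoms.T @ atoms)
        np.fill_diagonal(gram_abs, 0.0)
        usage = (codes != 0).sum(axis=1)
        n_replaced = 0
        for j in range(n_atoms):
            if usage[j] < min_usage or gram_abs[j].max() > coherence_limit:
                worst = int(np.argmax(col_err))
                col = training[:, worst]
                norm = np.linalg.norm(col)
                if norm <= 1e-12:
                    continue
                atoms[:, j] = col / norm
                codes[j, :] = 0.0
                col_err[worst] = 0.0
                gram_abs[j, :] = 0.0
                gram_abs[:, j] = 0.0
                n_replaced += 1
        if n_replaced:
            residual = training - atoms @ codes
        objective.append(float(np.linalg.norm(residual)))
        replacements.append(n_replaced)
        prev_codes = codes

    if return_info:
        return atoms, {"objective": objective, "replacements": replacements}
    return atoms


# ---------------------------------------------------------------------------
# end-to-end dictionary learning pipeline
# ---------------------------------------------------------------------------


def collect_training_patches(
    images: Sequence[np.ndarray], cfg: FusionConfig
) -> tuple[list[PatchSet], list[FeatureTable]]:
    """Enhance, multi-scale sample, patch and featurize the training images.

    Returns aligned patch sets and feature tables covering every
    (source, rate) combination, ready for :func:`build_training_sets`.
    """
    patch_sets: list[PatchSet] = []
    tables: list[FeatureTable] = []
    for l, img in enumerate(images):
        enhanced = enhance_details(img, cfg.enhance_levels, cfg.nd_window)
        for d in cfg.downsample_rates:
            sampled = downsample(enhanced, d)
            ps = extract_patches(
                sampled, cfg.patch_size, cfg.step, source=l, rate=d
            )
            sne = sne_map(sampled, cfg.sne_window)
            msf = msf_map(sampled, cfg.msf_scales, cfg.msf_weights, cfg.sf_mode)
            patch_sets.append(ps)
            tables.append(patch_features(ps, sne, msf))
    return patch_sets, tables


def learn_fusion_dictionary(
    images: Sequence[np.ndarray], cfg: FusionConfig | None = None
) -> Dictionary:
    """Train the full brightness+detail dictionary from registered sources.

    Runs the complete learning branch — detail enhancement, multi-scale
    sampling, SNE/MSF featurization, competitive training-set construction
    and two K-SVD runs — and concatenates the resulting blocks.
    """
    cfg = cfg or FusionConfig()
    if len(images) < 1:
        raise ValueError("at least one training image is required")
    shapes = {np.asarray(img).shape for img in images}
    if len(shapes) != 1:
        raise ValueError("training images must share dimensions")
    patch_sets, tables = collect_training_patches(images, cfg)
    sets = build_training_sets(patch_sets, tables)
    bright_atoms = ksvd_learn(
        sets.brightness,
        cfg.atoms_per_subdict,
        iterations=cfg.ksvd_iterations,
        tol=cfg.omp_tolerance,
        seed=cfg.rng_seed,
        max_atoms=cfg.max_atoms,
    )
    detail_atoms = ksvd_learn(
        sets.detail,
        cfg.atoms_per_subdict,
        iterations=cfg.ksvd_iterations,
        tol=cfg.omp_tolerance,
        seed=cfg.rng_seed + 1,
        max_atoms=cfg.max_atoms,
    )
    return assemble_dictionary(
        bright_atoms,
        detail_atoms,
        patch_size=cfg.patch_size,
        meta={"config": cfg.to_dict()},
    )
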