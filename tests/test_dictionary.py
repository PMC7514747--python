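import numpy as np
import pytest

from dictfuse import (
    Dictionary,
    FeatureTable,
    PatchSet,
    assemble_dictionary,
    build_training_sets,
    extract_patches,
    ksvd_learn,
    msf_map,
    omp_encode,
    omp_encode_batch,
    patch_features,
    sne_map,
)


def _patchset(vectors, source, rate):
    k = vectors.shape[1]
    return PatchSet(
        vectors=np.asarray(vectors, dtype=float),
        rows=np.zeros(k, dtype=int),
        cols=np.arange(k, dtype=int),
        patch_size=int(np.sqrt(vectors.shape[0])),
        step=1,
        image_shape=(8, 8 + k - 1),
        source=source,
        rate=rate,
    )


class TestBuildTrainingSets:
    def _featurize(self, img, source):
        ps = extract_patches(img, 8, 2, source=source, rate=1)
        table = patch_features(ps, sne_map(img, 5), msf_map(img, (3, 5, 7)))
        return ps, table

    def test_bright_vs_textured_sources(self, rng):
        bright = np.full((24, 24), 0.85) + rng.normal(0, 0.002, (24, 24))
        textured = 0.2 + 0.15 * (np.indices((24, 24)).sum(0) % 2)  # checkerboard
        ps_a, t_a = self._featurize(np.clip(bright, 0, 1), 0)
        ps_b, t_b = self._featurize(textured.astype(float), 1)
        sets = build_training_sets([ps_a, ps_b], [t_a, t_b])
        assert {p[0] for p in sets.brightness_provenance} == {0}
        assert {p[0] for p in sets.detail_provenance} == {1}
        assert sets.brightness.shape[1] == ps_a.n_patches
        assert sets.detail.shape[1] == ps_b.n_patches

    def test_identical_sources_deterministic_and_exclusive(self, rng):
        img = rng.random((24, 24))
        ps_a, t_a = self._featurize(img, 0)
        ps_b, t_b = self._featurize(img, 1)
        first = build_training_sets([ps_a, ps_b], [t_a, t_b])
        second = build_training_sets([ps_a, ps_b], [t_a, t_b])
        assert first.brightness_provenance == second.brightness_provenance
        assert first.detail_provenance == second.detail_provenance
        overlap = set(first.brightness_provenance) & set(first.detail_provenance)
        assert overlap == set()
        total = len(first.brightness_provenance) + len(first.detail_provenance)
        assert total <= 2 * ps_a.n_patches

    def test_hand_built_competition(self):
        # three slots; E and C winners chosen by explicit argmax
        vec = lambda v: np.full((64, 3), v)
        ps0, ps1 = _patchset(vec(0.1), 0, 1), _patchset(vec(0.9), 1, 1)
        t0 = FeatureTable(energy=[5.0, 1.0, 3.0], detail=[0.1, 9.0, 0.2])
        t1 = FeatureTable(energy=[2.0, 4.0, 8.0], detail=[0.3, 0.5, 7.0])
        sets = build_training_sets([ps0, ps1], [t0, t1])
        # E winners per slot: src0 (5>2), src1 (4>1), src1 (8>3)
        # C winners per slot: src1 (0.3>0.1), src0 (9>0.5), src1-conflict slot 2
        assert sets.brightness_provenance[:2] == [(0, 1, 0), (1, 1, 1)]
        assert sets.detail_provenance[:2] == [(1, 1, 0), (0, 1, 1)]
        # slot 2: source 1 wins both (E=8, C=7); exclusivity must hold
        slot2_b = [p for p in sets.brightness_provenance if p[2] == 2]
        slot2_d = [p for p in sets.detail_provenance if p[2] == 2]
        assert len(slot2_b) == 1 and len(slot2_d) == 1
        assert slot2_b[0] != slot2_d[0]

    def test_single_source_warns(self, rng):
        img = rng.random((24, 24))
        ps, table = self._featurize(img, 0)
        with pytest.warns(UserWarning, match="single source"):
            sets = build_training_sets([ps], [table])
        overlap = set(sets.brightness_provenance) & set(sets.detail_provenance)
        assert overlap == set()


class TestOMP:
    def test_exact_atom_hit(self, rng):
        atoms = rng.normal(size=(16, 32))
        atoms /= np.linalg.norm(atoms, axis=0)
        code = omp_encode(atoms[:, 3], atoms, tol=1e-8, max_atoms=4)
        assert code[3] == pytest.approx(1.0, abs=1e-10)
        assert np.abs(np.delete(code, 3)).max() < 1e-10

    def test_orthonormal_two_atom_recovery(self):
        atoms, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(16, 16)))
        y = 2.0 * atoms[:, 3] + 0.5 * atoms[:, 7]
        code = omp_encode(y, atoms, tol=1e-10, max_atoms=2)
        assert code[3] == pytest.approx(2.0, abs=1e-10)
        assert code[7] == pytest.approx(0.5, abs=1e-10)
        assert np.count_nonzero(code) == 2

    def test_stopping_contract(self, rng):
        atoms = rng.normal(size=(32, 64))
        atoms /= np.linalg.norm(atoms, axis=0)
        signals = rng.normal(size=(32, 50)) * 0.3
        codes = omp_encode_batch(signals, atoms, tol=0.1, max_atoms=8)
        residual = np.linalg.norm(signals - atoms @ codes, axis=0)
        support = (codes != 0).sum(axis=0)
        assert np.all((residual <= 0.1 + 1e-9) | (support == 8))

    def test_zero_signal_gives_zero_code(self, rng):
        atoms = rng.normal(size=(8, 16))
        atoms /= np.linalg.norm(atoms, axis=0)
        assert np.count_nonzero(omp_encode(np.zeros(8), atoms, 0.1, 4)) == 0

    def test_orthonormal_equals_thresholded_least_squares(self, rng):
        """For an orthonormal dictionary, s-step OMP keeps the s largest
        projections with their exact least-squares values."""
        atoms, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        y = rng.normal(size=12)
        s = 4
        code = omp_encode(y, atoms, tol=1e-12, max_atoms=s)
        proj = atoms.T @ y
        top = np.argsort(-np.abs(proj))[:s]
        expected = np.zeros(12)
        expected[top] = proj[top]
        assert np.allclose(code, expected, atol=1e-10)

    def test_matches_sklearn_pursuit(self, rng):
        """Independent oracle: scikit-learn's OMP follows the same greedy
        path on a well-conditioned dictionary."""
        from sklearn.linear_model import orthogonal_mp

        atoms = rng.normal(size=(24, 48))
        atoms /= np.linalg.norm(atoms, axis=0)
        signals = rng.normal(size=(24, 10))
        ours = omp_encode_batch(signals, atoms, tol=1e-10, max_atoms=6)
        theirs = orthogonal_mp(atoms, signals, n_nonzero_coefs=6)
        assert np.allclose(ours, theirs, atol=1e-8)

    def test_invalid_parameters(self, rng):
        atoms = rng.normal(size=(8, 16))
        atoms /= np.linalg.norm(atoms, axis=0)
        with pytest.raises(ValueError):
            omp_encode(np.zeros(8), atoms, tol=0.0, max_atoms=4)
        with pytest.raises(ValueError):
            omp_encode(np.zeros(8), atoms, tol=0.1, max_atoms=0)


class TestKSVD:
    def test_orthonormal_basis_recovery(self, rng):
        """Columns drawn from an orthonormal basis (plus tiny noise) are
        recovered as atoms up to sign/permutation."""
        basis, _ = np.linalg.qr(rng.normal(size=(16, 16)))
        basis = basis[:, :8]
        picks = rng.integers(0, 8, 300)
        signals = basis[:, picks] * rng.uniform(0.8, 1.2, 300)
        signals += rng.normal(0, 0.001, signals.shape)
        atoms = ksvd_learn(signals, 8, iterations=15, tol=0.01, seed=0, max_atoms=2)
        angles = np.degrees(np.arccos(np.clip(np.abs(basis.T @ atoms).max(axis=1), 0, 1)))
        assert angles.max() < 5.0

    def test_descent_contract(self, rng):
        basis = rng.normal(size=(16, 24))
        basis /= np.linalg.norm(basis, axis=0)
        signals = np.zeros((16, 200))
        for k in range(200):
            idx = rng.choice(24, 3, replace=False)
            signals[:, k] = basis[:, idx] @ rng.uniform(0.5, 1.5, 3)
        signals += rng.normal(0, 0.01, signals.shape)

        one = ksvd_learn(signals, 24, iterations=1, tol=0.1, seed=5, max_atoms=3)
        fifty, info = ksvd_learn(
            signals, 24, iterations=50, tol=0.1, seed=5, max_atoms=3, return_info=True
        )
        res = lambda d: np.linalg.norm(
            signals - d @ omp_encode_batch(signals, d, 0.1, 3)
        )
        assert res(fifty) <= res(one) + 1e-9
        # objective never increases across non-replacement iterations
        obj, rep = info["objective"], info["replacements"]
        for i in range(1, len(obj)):
            if rep[i] == 0:
                assert obj[i] <= obj[i - 1] + 1e-9

    def test_same_seed_bitwise_identical(self, rng):
        signals = rng.normal(size=(16, 80))
        a = ksvd_learn(signals, 12, iterations=5, tol=0.1, seed=3, max_atoms=4)
        b = ksvd_learn(signals, 12, iterations=5, tol=0.1, seed=3, max_atoms=4)
        assert np.array_equal(a, b)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="training columns"):
            ksvd_learn(rng.normal(size=(16, 8)), 12)
        with pytest.raises(ValueError, match="zero"):
            ksvd_learn(np.zeros((16, 40)), 12)

    def test_returned_atoms_unit_norm(self, rng):
        signals = rng.normal(size=(16, 80))
        atoms = ksvd_learn(signals, 12, iterations=3, tol=0.1, seed=1, max_atoms=4)
        assert np.allclose(np.linalg.norm(atoms, axis=0), 1.0, atol=1e-9)


class TestAssembleDictionary:
    def test_shapes_partition_and_norms(self, rng):
        blocks = []
        for _ in range(2):
            block = rng.normal(size=(64, 128))
            blocks.append(block / np.linalg.norm(block, axis=0))
        d = assemble_dictionary(blocks[0], blocks[1], patch_size=8)
        assert d.atoms.shape == (64, 256)
        assert d.n_brightness == 128
        assert np.array_equal(d.brightness_block, blocks[0])
        assert np.array_equal(d.detail_block, blocks[1])
        assert np.allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-9)

    def test_dimension_mismatch(self, rng):
        a = rng.normal(size=(64, 4))
        b = rng.normal(size=(49, 4))
        a /= np.linalg.norm(a, axis=0)
        b /= np.linalg.norm(b, axis=0)
        with pytest.raises(ValueError, match="dimensions differ"):
            assemble_dictionary(a, b)

    def test_unnormalized_atoms_rejected(self, rng):
        bad = rng.normal(size=(16, 8))
        with pytest.raises(ValueError, match="unit"):
            Dictionary(atoms=bad, n_brightness=4)

    def test_save_load_roundtrip(self, tmp_path, rng):
        block = rng.normal(size=(16, 24))
        block /= np.linalg.norm(block, axis=0)
        d = assemble_dictionary(block[:, :12], block[:, 12:], patch_size=4, meta={"k": 1})
        path = tmp_path / "dict.npz"
        d.save(path)
        back = Dictionary.load(path)
        assert np.array_equal(back.atoms, d.atoms)
        assert back.n_brightness == 12
        assert back.patch_size == 4
        assert back.meta == {"k": 1}
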