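import numpy as np
import pytest

from morphomod.simulate import generate_dataset
from morphomod.superimposition import (
    CRANIUM_PAIRING,
    MANDIBLE_PAIRING,
    PairingScheme,
    _rigid_fit,
    centroid_size,
    gpa,
    merge_views,
    procrustes_distance,
    read_pairing_file,
    reflect_relabel,
    symmetric_component,
)
from morphomod.io import LandmarkConfiguration

from conftest import make_dataset

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def rotation_2d(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def grid_search_procrustes_distance(a, b, n_grid=200_000):
    """Brute-force 2D Procrustes distance: minimise over rotation angle."""
    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt(np.sum(x**2))

    a, b = norm(a), norm(b)
    thetas = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    best = np.inf
    for t in thetas:
        d = np.sum((a - b @ rotation_2d(t)) ** 2)
        best = min(best, d)
    return np.sqrt(best)


class TestGpa:
    def test_identical_shapes_have_zero_distance_and_variance(self):
        res = gpa(np.stack([TRIANGLE, TRIANGLE.copy()]))
        assert np.allclose(res.aligned[0], res.aligned[1], atol=1e-12)
        assert procrustes_distance(TRIANGLE, TRIANGLE) < 1e-12

    def test_similarity_invariance(self):
        moved = 2.0 * TRIANGLE @ rotation_2d(np.pi / 2) + np.array([5.0, -3.0])
        assert procrustes_distance(TRIANGLE, moved) < 1e-9

    def test_distance_matches_grid_search_oracle(self):
        other = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        expected = grid_search_procrustes_distance(TRIANGLE, other)
        assert procrustes_distance(TRIANGLE, other) == pytest.approx(
            expected, abs=1e-6
        )

    def test_unit_centroid_size_and_centred(self, small_dataset):
        res = gpa(small_dataset)
        for cfg in res.aligned:
            assert centroid_size(cfg) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(cfg.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.consensus, res.aligned.mean(axis=0))

    def test_invariant_under_random_similarity_transforms(self, small_dataset, rng):
        res0 = gpa(small_dataset)
        coords = small_dataset.coords.copy()
        for i in range(coords.shape[0]):
            q, r = np.linalg.qr(rng.standard_normal((3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, [0, 1]] = q[:, [1, 0]]
            coords[i] = rng.uniform(0.5, 3.0) * coords[i] @ q + rng.uniform(
                -100, 100, 3
            )
        res1 = gpa(coords)
        # aligned shapes agree up to a common rotation of the whole set
        d = procrustes_distance(
            res0.aligned.reshape(-1, 3), res1.aligned.reshape(-1, 3)
        )
        assert d < 1e-7

    def test_residuals_never_increase_across_iterations(self, small_dataset):
        res = gpa(small_dataset)
        hist = np.asarray(res.residual_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((3, 2))
        with pytest.raises(ValueError, match="degenerate"):
            gpa(np.stack([flat, TRIANGLE]))


class TestMergeViews:
    def make_views(self, rng):
        full = rng.uniform(-10, 10, size=(10, 3))
        dorsal = LandmarkConfiguration("s", full[:6], view_tag="dorsal")
        ventral_lms = [0, 1, 5, 6, 7, 8, 9]  # refs 0,1,5 shared
        return full, dorsal, ventral_lms

    def test_identity_when_frames_agree(self, rng):
        full, dorsal, vlms = self.make_views(rng)
        ventral = LandmarkConfiguration("s", full[vlms], view_tag="ventral")
        merged, rms = merge_views(dorsal, ventral, [0, 1, 5], [0, 1, 2])
        np.testing.assert_allclose(merged.coords, full, atol=1e-9)
        assert rms < 1e-9

    def test_recovers_known_rigid_transform(self, rng):
        full, dorsal, vlms = self.make_views(rng)
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, [0, 1]] = q[:, [1, 0]]
        t = np.array([3.0, -7.0, 11.0])
        ventral = LandmarkConfiguration("s", full[vlms] @ q + t)
        rot, trans = _rigid_fit(ventral.coords[[0, 1, 2]], dorsal.coords[[0, 1, 5]])
        np.testing.assert_allclose(rot, q.T, atol=1e-9)
        np.testing.assert_allclose(trans, -t @ q.T, atol=1e-9)
        merged, rms = merge_views(dorsal, ventral, [0, 1, 5], [0, 1, 2])
        np.testing.assert_allclose(merged.coords, full, atol=1e-9)

    def test_collinear_references_rejected(self):
        dorsal = LandmarkConfiguration(
            "s", np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], float)
        )
        ventral = LandmarkConfiguration(
            "s", np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 5, 5]], float)
        )
        with pytest.raises(ValueError, match="collinear"):
            merge_views(dorsal, ventral, [0, 1, 2], [0, 1, 2])

    def test_too_few_references_rejected(self, rng):
        full, dorsal, vlms = self.make_views(rng)
        ventral = LandmarkConfiguration("s", full[vlms])
        with pytest.raises(ValueError, match="at least 3"):
            merge_views(dorsal, ventral, [0, 1], [0, 1])


class TestSymmetricComponent:
    def test_mirror_symmetric_input_has_zero_asymmetry(
        self, small_symmetric_config
    ):
        cfg = small_symmetric_config
        cfg.asymmetry_sd = 0.0
        ds = generate_dataset(cfg)
        decomp = symmetric_component(gpa(ds), cfg.pairing)
        assert np.abs(decomp.asymmetric).max() < 1e-9

    def test_reconstruction_is_exact(self, small_dataset, small_pairing):
        decomp = symmetric_component(gpa(small_dataset), small_pairing)
        np.testing.assert_allclose(
            decomp.symmetric + decomp.asymmetric, decomp.aligned, atol=1e-12
        )

    def test_symmetric_component_is_reflection_fixed_point(
        self, small_dataset, small_pairing
    ):
        decomp = symmetric_component(gpa(small_dataset), small_pairing)
        for sym in decomp.symmetric:
            reflected = reflect_relabel(sym, small_pairing)
            assert procrustes_distance(sym, reflected) < 1e-9

    def test_asymmetry_grows_with_injected_displacement(
        self, small_symmetric_config, small_pairing
    ):
        cfg = small_symmetric_config
        cfg.asymmetry_sd = 0.0
        ds = generate_dataset(cfg)
        magnitudes = []
        for delta in [0.0, 0.5, 1.0, 2.0]:
            coords = ds.coords.copy()
            coords[:, small_pairing.paired[0][0], 1] += delta  # one side only
            decomp = symmetric_component(gpa(coords), small_pairing)
            magnitudes.append(float(np.sqrt(np.mean(decomp.asymmetric**2))))
        assert all(np.diff(magnitudes) > 0)

    def test_pairing_must_partition(self, small_dataset):
        bad = PairingScheme(paired=((0, 1),), midline=(2,))
        with pytest.raises(ValueError, match="partition"):
            symmetric_component(gpa(small_dataset), bad)


class TestPairingSchemes:
    def test_bundled_schemes_partition(self):
        CRANIUM_PAIRING.validate(62)
        MANDIBLE_PAIRING.validate(24)

    def test_pairing_file_round_trip(self, tmp_path):
        lines = ["1 2", "3 4", "5", "6"]
        p = tmp_path / "pairing.txt"
        p.write_text("\n".join(lines) + "\n")
        scheme = read_pairing_file(p)
        assert scheme.paired == ((0, 1), (2, 3))
        assert scheme.midline == (4, 5)
        scheme.validate(6)
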