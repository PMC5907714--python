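import numpy as np
import pytest

from morphomod.modularity import (
    CorrelationMatrix,
    ModelSpec,
    ModuleHypothesis,
    build_model_set,
    emmli_fit,
    eigenvalue_dispersion,
    eigenvalue_dispersion_from_corr,
    integration_report,
    compare_wild_domestic,
    landmark_correlation_matrix,
    load_bundled_hypotheses,
    module_disparity,
    read_hypothesis_file,
)


def block_correlation_data(rng, k=20, n=100, block=range(10), rho_in=0.8, rho_bg=0.2):
    """n x k x 1 'coordinates' whose landmark correlations are block-structured."""
    cov = np.full((k, k), rho_bg)
    idx = np.array(list(block))
    cov[np.ix_(idx, idx)] = rho_in
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    return X[:, :, None]


class TestLandmarkCorrelationMatrix:
    def test_62_landmarks_give_1891_correlations(self, rng):
        corr = landmark_correlation_matrix(rng.standard_normal((10, 62, 3)))
        assert corr.n_corr == 1891
        assert corr.values.shape == (62, 62)
        assert np.all(np.diag(corr.values) == 1.0)
        assert np.all((corr.values >= 0) & (corr.values <= 1.0 + 1e-12))

    def test_identically_displaced_landmarks_fully_correlated(self, rng):
        dev = rng.standard_normal((30, 1, 2))
        coords = np.concatenate([dev, dev + 5.0, rng.standard_normal((30, 1, 2))], axis=1)
        corr = landmark_correlation_matrix(coords)
        assert corr.values[0, 1] == pytest.approx(1.0)

    def test_null_mean_matches_simulation_oracle(self):
        """Independent isotropic noise: mean |r| agrees with a direct MC oracle."""
        rng = np.random.default_rng(41)
        n, k, m = 500, 10, 2
        corr = landmark_correlation_matrix(rng.standard_normal((n, k, m)))
        iu = np.triu_indices(k, 1)
        observed = corr.values[iu].mean()
        # oracle: |congruence| of independent centred Gaussian deviation vectors
        oracle_rng = np.random.default_rng(42)
        sims = []
        for _ in range(2000):
            u = oracle_rng.standard_normal((n, m))
            v = oracle_rng.standard_normal((n, m))
            u -= u.mean(axis=0)
            v -= v.mean(axis=0)
            sims.append(
                abs(np.sum(u * v)) / (np.linalg.norm(u) * np.linalg.norm(v))
            )
        expected = np.mean(sims)
        assert observed == pytest.approx(expected, abs=3 * np.std(sims) / np.sqrt(len(iu[0])) + 0.004)

    def test_zero_variance_landmark_named(self, rng):
        coords = rng.standard_normal((10, 4, 2))
        coords[:, 2, :] = 1.5
        with pytest.raises(ValueError, match="landmark 2"):
            landmark_correlation_matrix(coords)


class TestEmmliFit:
    def two_module_hypothesis(self, k=20, split=10):
        return ModuleHypothesis(
            "two", {i: ("m1" if i < split else "m2") for i in range(k)}
        )

    def test_model_set_has_17_models(self):
        hyps = list(load_bundled_hypotheses().values())
        models = build_model_set(hyps)
        assert len(models) == 17
        assert sum(m.hypothesis is None for m in models) == 1

    def test_block_structure_recovered(self, rng):
        coords = block_correlation_data(rng)
        corr = landmark_correlation_matrix(coords)
        hyp = self.two_module_hypothesis()
        wrong = ModuleHypothesis(
            "interleaved", {i: ("m1" if i % 2 == 0 else "m2") for i in range(20)}
        )
        fits = emmli_fit(corr, build_model_set([hyp, wrong]))
        best = fits[0]
        assert best.model.hypothesis is hyp
        # one elevated block needs separate within-module correlations; for two
        # modules variants c and d imply the same partition, so they tie
        assert best.model.variant in ("c", "d")
        assert best.dAICc == 0.0
        assert all(
            f.model.hypothesis is hyp for f in fits if f.dAICc < 1e-9
        )
        # estimated correlations land near the generating levels
        rho_within_m1 = [v for s, v in best.rho_hat.items() if s.startswith("within.m1")]
        assert rho_within_m1[0] == pytest.approx(0.8, abs=0.1)

    def test_nested_models_likelihood_ordering(self, rng):
        coords = block_correlation_data(rng)
        corr = landmark_correlation_matrix(coords)
        hyp = self.two_module_hypothesis()
        fits = {
            f.model.variant: f
            for f in emmli_fit(
                corr, [ModelSpec(hyp, v) for v in "abcd"] + [ModelSpec(None, None)]
            )
            if f.model.hypothesis is not None
        }
        assert fits["d"].logL >= fits["a"].logL - 1e-9
        assert fits["d"].logL >= fits["b"].logL - 1e-9
        assert fits["d"].logL >= fits["c"].logL - 1e-9
        assert fits["d"].K > fits["a"].K

    def test_uniform_correlations_favor_null(self):
        k = 12
        values = np.full((k, k), 0.4)
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix(values=values, sample_size=100)
        hyp = self.two_module_hypothesis(k=k, split=6)
        fits = emmli_fit(corr, build_model_set([hyp]))
        best = fits[0]
        assert best.model.hypothesis is None  # no structure: null wins on parsimony
        # all models explain equal correlations equally well
        logls = [f.logL for f in fits]
        assert max(logls) - min(logls) < 1e-6

    def test_parameter_counts(self):
        hyp = self.two_module_hypothesis()
        corr = CorrelationMatrix(
            values=np.eye(20) * 0.0 + np.full((20, 20), 0.3), sample_size=50
        )
        np.fill_diagonal(corr.values, 1.0)
        fits = {f.model.name: f for f in emmli_fit(corr, build_model_set([hyp]))}
        assert fits["null"].K == 2
        assert fits["two.a"].K == 3  # within + between + 1
        assert fits["two.d"].K == 4  # 2 within + 1 between + 1
        assert fits["null"].K < fits["two.d"].K


class TestEigenvalueDispersion:
    def test_complete_integration_is_one(self):
        assert eigenvalue_dispersion_from_corr(np.ones((6, 6))) == pytest.approx(1.0)

    def test_no_integration_is_zero(self):
        assert eigenvalue_dispersion_from_corr(np.eye(9)) == pytest.approx(0.0)

    def test_compound_symmetry_equals_rho(self):
        """For exchangeable correlation rho the dispersion equals rho exactly."""
        for rho in [0.2, 0.5, 0.8]:
            corr = np.full((7, 7), rho)
            np.fill_diagonal(corr, 1.0)
            assert eigenvalue_dispersion_from_corr(corr) == pytest.approx(rho)

    def test_invariant_under_permutation_and_scaling(self, rng):
        coords = rng.standard_normal((40, 5, 2))
        psi0 = eigenvalue_dispersion(coords)
        perm = rng.permutation(5)
        assert eigenvalue_dispersion(coords[:, perm, :]) == pytest.approx(psi0)
        assert eigenvalue_dispersion(3.7 * coords) == pytest.approx(psi0)

    def test_too_few_variables_rejected(self, rng):
        with pytest.raises(ValueError):
            eigenvalue_dispersion_from_corr(np.ones((1, 1)))


class TestModuleDisparity:
    def test_identical_configurations_zero(self):
        coords = np.tile(np.arange(8.0).reshape(4, 2), (6, 1, 1))
        assert module_disparity(coords) == (0.0, 0.0)

    def test_single_outlier_distances(self):
        """One displaced specimen: distances follow from the mean shift."""
        n, delta = 10, np.full((3, 2), 2.0)
        base = np.arange(6.0).reshape(3, 2)
        coords = np.tile(base, (n, 1, 1))
        coords[0] += delta
        d = np.linalg.norm(delta)
        d_max, d_mean = module_disparity(coords)
        # mean configuration sits delta/n from the crowd
        assert d_max == pytest.approx(d * (n - 1) / n)
        assert d_mean == pytest.approx(
            (d * (n - 1) / n + (n - 1) * d / n) / n
        )
        assert d_max >= d_mean


class TestIntegrationReports:
    def test_identical_subsets_identical_reports(self, rng):
        coords = rng.standard_normal((12, 9, 3)) + 10
        both = np.concatenate([coords, coords])
        groups = np.array(["H"] * 12 + ["Z"] * 12)
        hyp = ModuleHypothesis(
            "h", {i: ("a" if i < 4 else "b") for i in range(9)}
        )
        reports = compare_wild_domestic(
            both, groups, hyp, wild_groups=("Z",), domestic_groups=("H",)
        )
        assert reports["wild"].average_psi == pytest.approx(
            reports["domestic"].average_psi
        )
        np.testing.assert_allclose(
            reports["wild"].per_module["disparity_max"],
            reports["domestic"].per_module["disparity_max"],
        )

    def test_tiny_subset_rejected(self, rng):
        coords = rng.standard_normal((5, 6, 2))
        groups = np.array(["H"] * 4 + ["Z"])
        hyp = ModuleHypothesis("h", {i: "a" for i in range(6)})
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_wild_domestic(coords, groups, hyp, wild_groups=("Z",))


class TestHypothesisIO:
    def test_bundled_hypotheses_cover_cranium(self):
        hyps = load_bundled_hypotheses()
        assert set(hyps) == {
            "tissue_origin",
            "mammalian_six",
            "functional",
            "horse_specific",
        }
        for hyp in hyps.values():
            hyp.validate(62)
        assert set(hyps["mammalian_six"].modules) == {
            "AON", "CB", "CV", "MR", "ORB", "ZP",
        }
        assert len(hyps["tissue_origin"].modules) == 2

    def test_hypothesis_file_round_trip(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("1 a\n2 a\n3 b\n")
        hyp = read_hypothesis_file(p, "h")
        assert hyp.assignment == {0: "a", 1: "a", 2: "b"}
        hyp.validate(3)
        with pytest.raises(ValueError):
            read_hypothesis_file(tmp_path / "h.txt").validate(4)
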