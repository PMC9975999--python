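"""FIML Cholesky machinery: implied moments, likelihood, gradient, fitting,
standardization, model comparison and Falconer moment estimates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinfear as tf
import twinfear.biometric_model as bm
from twinfear.synthetic_data import GeneratingModel, SamplePlan


def random_params(spec, seed=0, scale=0.5):
    rng = np.random.default_rng(seed)
    tril = np.tril_indices(3)

    def L():
        M = np.zeros((3, 3))
        M[tril] = rng.normal(0.3, scale, 6)
        return M

    return bm.CholeskyParams(
        L_A=L(), L_E=L(), mu=rng.normal(0, 1, 3),
        L_C=L() if spec.has_c else None,
    )


def small_table(seed=0, n_mz=8, n_dz=8, n_single=4):
    model = tf.paper_generating_model(plan=SamplePlan(n_mz, n_dz, n_single // 2, n_single - n_single // 2))
    return tf.simulate_twin_phenotypes(model, seed=seed)


class TestImpliedCovariance:
    def test_identity_loadings(self):
        spec = bm.ModelSpec("ACE")
        I = np.eye(3)
        params = bm.CholeskyParams(L_A=I, L_C=I, L_E=I, mu=np.zeros(3))
        for zyg, cross in (("MZ", 2.0), ("DZ", 1.5)):
            sigma, mu6 = bm.implied_covariance(params, spec, zyg)
            np.testing.assert_allclose(sigma[:3, :3], 3 * I)
            np.testing.assert_allclose(sigma[:3, 3:], cross * I)
            np.testing.assert_allclose(mu6, 0.0)

    def test_ae_diagonal_shares(self):
        spec = bm.ModelSpec("AE")
        params = bm.CholeskyParams(
            L_A=np.diag(np.sqrt([0.3] * 3)), L_E=np.diag(np.sqrt([0.7] * 3)),
            mu=np.zeros(3),
        )
        for zyg, cross in (("MZ", 0.3), ("DZ", 0.15)):
            sigma, _ = bm.implied_covariance(params, spec, zyg)
            np.testing.assert_allclose(np.diag(sigma), 1.0)
            np.testing.assert_allclose(sigma[:3, 3:], cross * np.eye(3), atol=1e-15)

    @pytest.mark.parametrize("variant", ["ACE", "AE"])
    @pytest.mark.parametrize("seed", range(5))
    def test_block_structure_random_params(self, variant, seed):
        """MZ cross-block = A + C and DZ cross-block = 0.5 A + C hold
        exactly; the matrix is symmetric and PSD by construction."""
        spec = bm.ModelSpec(variant)
        params = random_params(spec, seed=seed)
        A = params.component("A")
        C = params.component("C") if spec.has_c else np.zeros((3, 3))
        E = params.component("E")
        for zyg, alpha in (("MZ", 1.0), ("DZ", 0.5)):
            sigma, _ = bm.implied_covariance(params, spec, zyg)
            np.testing.assert_allclose(sigma[:3, :3], A + C + E, atol=1e-14)
            np.testing.assert_allclose(sigma[3:, 3:], A + C + E, atol=1e-14)
            np.testing.assert_allclose(sigma[:3, 3:], alpha * A + C, atol=1e-14)
            np.testing.assert_array_equal(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10


class TestLikelihood:
    def test_complete_family_closed_form(self):
        """Identity implied covariance, zero means, zero data: each complete
        family contributes 6 ln(2 pi)."""
        spec = bm.ModelSpec("ACE")
        # S = A + C + E = I with A = C = 0, E = I
        params = bm.CholeskyParams(
            L_A=np.zeros((3, 3)), L_C=np.zeros((3, 3)), L_E=np.eye(3),
            mu=np.zeros(3))
        table = pd.DataFrame([{
            "family_id": "F1", "zygosity": "MZ",
            **{f"t{k}_{t}": 0.0 for k in (1, 2) for t in tf.TRAITS},
        }])
        nll = bm.neg2_log_likelihood(params, spec, table)
        assert nll == pytest.approx(6 * np.log(2 * np.pi), abs=1e-10)

    def test_singleton_row_filtering(self):
        spec = bm.ModelSpec("AE")
        params = bm.CholeskyParams(L_A=np.zeros((3, 3)), L_E=np.eye(3), mu=np.zeros(3))
        table = pd.DataFrame([{
            "family_id": "F1", "zygosity": "DZ",
            **{f"t1_{t}": 0.0 for t in tf.TRAITS},
            **{f"t2_{t}": np.nan for t in tf.TRAITS},
        }])
        nll = bm.neg2_log_likelihood(params, spec, table)
        assert nll == pytest.approx(3 * np.log(2 * np.pi), abs=1e-10)

    def test_moment_form_equals_complete_data_formula(self):
        """On complete pairs the FIML sum equals the closed-form expression
        N (k ln 2pi + ln|S| + tr(S^-1 S_ml) + (xbar-mu)' S^-1 (xbar-mu))."""
        model = tf.paper_generating_model(plan=SamplePlan(500, 0, 0, 0))
        table = tf.simulate_twin_phenotypes(model, seed=11)
        table = table[table["zygosity"] == "MZ"]
        spec = bm.ModelSpec("AE")
        params = random_params(spec, seed=2)
        sigma, mu6 = bm.implied_covariance(params, spec, "MZ")
        X = table[[f"t{k}_{t}" for k in (1, 2) for t in tf.TRAITS]].to_numpy()
        # column order here is t1 traits then t2 traits, matching mu6
        N = len(X)
        xbar = X.mean(axis=0)
        S_ml = (X - xbar).T @ (X - xbar) / N
        Sinv = np.linalg.inv(sigma)
        d = xbar - mu6
        expected = N * (
            6 * np.log(2 * np.pi) + np.linalg.slogdet(sigma)[1]
            + np.trace(Sinv @ S_ml) + d @ Sinv @ d
        )
        got = bm.neg2_log_likelihood(params, spec, table)
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("variant", ["ACE", "AE"])
    def test_gradient_matches_finite_differences(self, variant):
        spec = bm.ModelSpec(variant)
        groups = bm.family_groups(small_table(seed=3))
        rng = np.random.default_rng(0)
        theta = rng.normal(0.4, 0.3, spec.n_params)
        _, g = bm._nll_grad(theta, spec, groups)
        h = 1e-4  # central differences; smaller steps hit roundoff at |f| ~ 1e4
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (bm._nll_grad(tp, spec, groups)[0] - bm._nll_grad(tm, spec, groups)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    @pytest.mark.parametrize("column", [0, 1, 2])
    def test_column_sign_flip_invariance(self, column):
        """Flipping the sign of any Cholesky column leaves the likelihood
        unchanged (A = L L' is invariant), justifying the post-fit sign
        convention."""
        spec = bm.ModelSpec("AE")
        groups = bm.family_groups(small_table(seed=4))
        params = random_params(spec, seed=5)
        base = bm.neg2_log_likelihood(params, spec, groups)
        for attr in ("L_A", "L_E"):
            flipped_L = getattr(params, attr).copy()
            flipped_L[:, column] *= -1.0
            flipped = bm.CholeskyParams(
                L_A=flipped_L if attr == "L_A" else params.L_A,
                L_E=flipped_L if attr == "L_E" else params.L_E,
                mu=params.mu,
            )
            assert bm.neg2_log_likelihood(flipped, spec, groups) == pytest.approx(base, abs=1e-9)

    def test_singular_covariance_penalized_not_raised(self):
        spec = bm.ModelSpec("AE")
        params = bm.CholeskyParams(L_A=np.zeros((3, 3)), L_E=np.zeros((3, 3)), mu=np.zeros(3))
        nll = bm.neg2_log_likelihood(params, spec, small_table(seed=6))
        assert np.isfinite(nll) and nll >= 1e11


class TestFit:
    def test_recovers_diagonal_ae_structure(self):
        """a2 = 0.3 per trait with rA = rE = I, 20k pairs per zygosity:
        estimates land within 0.02 of truth."""
        model = GeneratingModel(variant="AE", a2=(0.3, 0.3, 0.3),
                                plan=SamplePlan(20_000, 20_000, 0, 0))
        table = tf.simulate_twin_phenotypes(model, seed=12)
        fit = tf.fit_model(table, "AE")
        assert fit.converged
        sol = tf.standardize(fit.params, fit.spec)
        np.testing.assert_allclose(sol.a2, 0.3, atol=0.02)

    def test_ace_never_fits_worse_than_ae(self, small_model):
        table = tf.simulate_twin_phenotypes(small_model, seed=13)
        fae = tf.fit_model(table, "AE")
        face = tf.fit_model(table, "ACE")
        assert face.minus2LL <= fae.minus2LL + 1e-6

    def test_mz_only_raises_identifiability_error(self):
        model = tf.paper_generating_model(plan=SamplePlan(20, 0, 0, 0))
        table = tf.simulate_twin_phenotypes(model, seed=1)
        with pytest.raises(ValueError, match="zygosity"):
            tf.fit_model(table, "AE")

    def test_aic_accounting(self, small_model):
        table = tf.simulate_twin_phenotypes(small_model, seed=14)
        fit = tf.fit_model(table, "AE")
        assert fit.AIC == pytest.approx(fit.minus2LL + 2 * 15)
        assert fit.n_params == 15

    def test_fit_uses_missing_phenotypes(self, small_model):
        """Families with partly missing phenotypes still contribute."""
        table = tf.simulate_twin_phenotypes(small_model, seed=15)
        table.loc[table.index[:20], "t2_consol"] = np.nan
        fit = tf.fit_model(table, "AE")
        assert fit.converged
        assert fit.data_summary["n_families"] == len(table)


class TestStandardize:
    def test_diagonal_components_give_identity_correlations(self):
        spec = bm.ModelSpec("AE")
        params = bm.CholeskyParams(
            L_A=np.diag([0.5, 0.6, 0.7]), L_E=np.diag([0.8, 0.7, 0.6]),
            mu=np.zeros(3))
        sol = tf.standardize(params, spec)
        np.testing.assert_allclose(sol.rA, np.eye(3), atol=1e-14)
        np.testing.assert_allclose(sol.rE, np.eye(3), atol=1e-14)
        np.testing.assert_allclose(sol.r_phenotypic, np.eye(3), atol=1e-14)

    def test_hand_computed_case(self):
        A = np.array([[0.30, 0.15, 0.06],
                      [0.15, 0.30, 0.06],
                      [0.06, 0.06, 0.15]])
        E = np.array([[0.70, 0.10, 0.02],
                      [0.10, 0.70, 0.02],
                      [0.02, 0.02, 0.85]])
        spec = bm.ModelSpec("AE")
        params = bm.CholeskyParams(
            L_A=np.linalg.cholesky(A), L_E=np.linalg.cholesky(E), mu=np.zeros(3))
        sol = tf.standardize(params, spec)
        # hand arithmetic: S = A + E has unit diagonal
        np.testing.assert_allclose(sol.a2, [0.30, 0.30, 0.15], atol=1e-12)
        np.testing.assert_allclose(sol.e2, [0.70, 0.70, 0.85], atol=1e-12)
        assert sol.rA[0, 1] == pytest.approx(0.15 / 0.30, abs=1e-12)
        assert sol.rA[0, 2] == pytest.approx(0.06 / np.sqrt(0.30 * 0.15), abs=1e-12)
        assert sol.r_phenotypic[0, 1] == pytest.approx(0.25, abs=1e-12)
        assert sol.contrib_A[0, 1] == pytest.approx(0.15, abs=1e-12)

    def test_contribution_identity_for_fitted_model(self, small_model):
        table = tf.simulate_twin_phenotypes(small_model, seed=16)
        fit = tf.fit_model(table, "AE")
        sol = tf.standardize(fit.params, fit.spec)
        np.testing.assert_allclose(
            sol.contrib_A + sol.contrib_E, sol.r_phenotypic, atol=1e-10)
        np.testing.assert_allclose(sol.a2 + sol.e2, 1.0, atol=1e-12)


class TestCompareModels:
    def test_identical_fits(self, small_model):
        table = tf.simulate_twin_phenotypes(small_model, seed=17)
        fae = tf.fit_model(table, "AE")
        face = bm.FitResult(
            params=fae.params, spec=bm.ModelSpec("ACE"),
            minus2LL=fae.minus2LL, n_params=bm.ModelSpec("ACE").n_params,
            converged=True, n_iter=0, grad_norm=0.0,
            data_summary=fae.data_summary)
        cmp = tf.compare_models(face, fae)
        assert cmp["chi2"] == pytest.approx(0.0)
        assert cmp["df"] == 6
        assert cmp["delta_AIC"] == pytest.approx(-12.0)

    def test_p_value_quantile(self):
        # chi2 = 12.59 on 6 df sits at p ~ 0.05
        assert stats.chi2.sf(12.59, 6) == pytest.approx(0.05, abs=5e-4)

    def test_different_data_rejected(self, small_model):
        t1 = tf.simulate_twin_phenotypes(small_model, seed=18)
        t2 = tf.simulate_twin_phenotypes(small_model, seed=19)
        face = tf.fit_model(t1, "ACE")
        fae = tf.fit_model(t2, "AE")
        with pytest.raises(ValueError, match="different data"):
            tf.compare_models(face, fae)


class TestFalconer:
    @pytest.mark.parametrize(
        "rmz,rdz,expected",
        [
            (0.30, 0.15, (0.30, 0.00, 0.70)),
            (0.50, 0.40, (0.20, 0.30, 0.50)),
        ],
    )
    def test_point_values(self, rmz, rdz, expected):
        a2, c2, e2 = tf.falconer_estimates(rmz, rdz)
        np.testing.assert_allclose([a2, c2, e2], expected, atol=1e-12)

    def test_negative_raw_clipped_for_starts(self):
        a2_raw, _, _ = tf.falconer_estimates(0.1, 0.2)
        assert a2_raw == pytest.approx(-0.2)
        a2_c, c2_c, e2_c = tf.falconer_estimates(0.1, 0.2, clip=True)
        assert a2_c == 0.0
        assert a2_c + c2_c + e2_c == pytest.approx(1.0)


class TestBootstrapModelCI:
    def test_deterministic_under_seed(self, small_model):
        table = tf.simulate_twin_phenotypes(small_model, seed=20)
        _, s1 = tf.bootstrap_model_ci(table, "AE", n_iter=12, seed=77)
        _, s2 = tf.bootstrap_model_ci(table, "AE", n_iter=12, seed=77)
        for key in s1.cis:
            np.testing.assert_array_equal(s1.cis[key][0], s2.cis[key][0])
            np.testing.assert_array_equal(s1.cis[key][1], s2.cis[key][1])

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for label, plan in (("small", SamplePlan(100, 100, 0, 0)),
                            ("large", SamplePlan(1000, 1000, 0, 0))):
            model = tf.paper_generating_model(plan=plan)
            table = tf.simulate_twin_phenotypes(model, seed=21)
            _, sol = tf.bootstrap_model_ci(table, "AE", n_iter=60, seed=3)
            w = []
            for key in ("a2", "e2", "rA", "rE", "r_phenotypic"):
                lo, hi = sol.cis[key]
                w.extend(np.asarray(hi - lo).ravel())
            widths[label] = np.array(w)
        finite = np.isfinite(widths["small"]) & np.isfinite(widths["large"])
        frac = np.mean(widths["large"][finite] < widths["small"][finite] + 1e-12)
        assert frac >= 0.95
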