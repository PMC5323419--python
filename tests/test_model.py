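"""Tests of the REML engine: design assembly, marginal covariance, GLS,
standard errors, criterion correctness against a dense oracle, and
statistical behaviour of the fits."""

import numpy as np
import pandas as pd
import pytest

from mlmct.ar import build_ar1_sigma, build_whitening_ar1
from mlmct.model import (
    MultilevelModel,
    RandomEffectsCov,
    ResidualStructure,
    assemble_design,
    fixed_effect_se,
    gls_fixed_effects,
    marginal_covariance,
    reml_fit,
)
from mlmct.simulation import SimulationCondition, TrueParameters, _generate_arrays


def _dense_reml_loglik(y_blocks, X_blocks, Sigma_blocks):
    """Independent dense evaluation of the REML log-likelihood:
    -0.5 [ sum log|Sigma_i| + log|X'S^-1X| + r'S^-1r + (n-k) log 2pi ]."""
    k = X_blocks[0].shape[1]
    n = sum(len(y) for y in y_blocks)
    info = np.zeros((k, k))
    xty = np.zeros(k)
    logdet = 0.0
    for y, X, S in zip(y_blocks, X_blocks, Sigma_blocks):
        Si = np.linalg.inv(S)
        info += X.T @ Si @ X
        xty += X.T @ Si @ y
        logdet += np.linalg.slogdet(S)[1]
    gamma = np.linalg.solve(info, xty)
    quad = 0.0
    for y, X, S in zip(y_blocks, X_blocks, Sigma_blocks):
        r = y - X @ gamma
        quad += r @ np.linalg.solve(S, r)
    return -0.5 * (
        logdet + np.linalg.slogdet(info)[1] + quad + (n - k) * np.log(2 * np.pi)
    )


class TestAssembleDesign:
    def test_hand_expansion(self):
        panel = pd.DataFrame(
            {
                "subject": [1, 1, 1],
                "occasion": [1, 2, 3],
                "y": [0.0, 0.0, 0.0],
                "z": [0.0, 1.0, 2.0],
                "c": [2.0, 2.0, 2.0],
            }
        )
        _, _, Xs, Zs = assemble_design(panel)
        np.testing.assert_allclose(
            Xs[0], [[1, 0, 2, 0], [1, 1, 2, 2], [1, 2, 2, 4]]
        )
        np.testing.assert_allclose(Zs[0], [[1, 0], [1, 1], [1, 2]])

    def test_zero_level2_covariate_zeroes_columns(self, small_panel):
        p = small_panel.copy()
        p.loc[p["subject"] == 1, "c"] = 0.0
        _, _, Xs, _ = assemble_design(p)
        assert np.all(Xs[0][:, 2:] == 0.0)

    def test_varying_level2_covariate_rejected(self, small_panel):
        p = small_panel.copy()
        p.loc[0, "c"] = 99.0
        with pytest.raises(ValueError, match="varies within subject"):
            assemble_design(p)

    def test_transformed_panel_columns_taken_verbatim(self):
        """A serialized whitened panel round-trips into blocks without any
        intercept injection."""
        from mlmct.simulation import generate_dataset
        from mlmct.transform import mlm_ct_pipeline

        panel = generate_dataset(
            SimulationCondition(3, 15, 0.5, base_seed=19), TrueParameters(), 0
        )
        tp = mlm_ct_pipeline(panel, p=1)
        frame = tp.to_frame()
        _, ys, Xs, Zs = assemble_design(frame, transformed=True)
        for i in range(3):
            np.testing.assert_allclose(ys[i], tp.y_blocks[i])
            np.testing.assert_allclose(Xs[i], tp.X_blocks[i])
            np.testing.assert_allclose(Zs[i], tp.Z_blocks[i])
            assert not np.allclose(Xs[i][:, 0], 1.0)  # transformed intercept


class TestMarginalCovariance:
    def test_null_G_id_residuals(self):
        Z = np.column_stack([np.ones(4), np.arange(4.0)])
        S = marginal_covariance(np.zeros((2, 2)), ResidualStructure("id", 2.0), Z)
        np.testing.assert_allclose(S, 2.0 * np.eye(4))

    def test_random_intercept_id_equals_null_G_compound_symmetry(self):
        """A random-intercept-only G with ID residuals implies the same
        marginal covariance as no random effects with compound symmetry."""
        Z = np.column_stack([np.ones(5), np.zeros(5)])
        G = np.array([[0.7, 0.0], [0.0, 0.0]])
        S1 = marginal_covariance(G, ResidualStructure("id", 1.3), Z)
        S_cs = 1.3 * np.eye(5) + 0.7 * np.ones((5, 5))
        np.testing.assert_allclose(S1, S_cs, atol=1e-12)

    def test_positive_definite_for_random_draws(self, rng):
        Z = np.column_stack([np.ones(6), rng.standard_normal(6)])
        for _ in range(100):
            v0, v1 = rng.uniform(0.01, 2.0, 2)
            cov = rng.uniform(-1, 1) * np.sqrt(v0 * v1)
            G = np.array([[v0, cov], [cov, v1]])
            rho = rng.uniform(-0.9, 0.9)
            S = marginal_covariance(G, ResidualStructure("ar1", 1.0, rho), Z)
            assert np.linalg.eigvalsh(S).min() > 0

    def test_invalid_G_rejected(self):
        with pytest.raises(ValueError):
            RandomEffectsCov(0.1, 0.1, 0.5)


class TestGLS:
    def test_identity_sigma_equals_ols(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        y = rng.standard_normal(10)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(gls_fixed_effects(y, X, np.eye(10)), ols, atol=1e-10)

    def test_equals_whitened_ols_for_ar1_sigma(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        Sigma = build_ar1_sigma(0.6, 1.0, n)
        op = build_whitening_ar1(0.6, n)
        beta_w, *_ = np.linalg.lstsq(op.apply(X), op.apply(y[:, None])[:, 0], rcond=None)
        np.testing.assert_allclose(gls_fixed_effects(y, X, Sigma), beta_w, atol=1e-8)

    def test_duplicated_column_rejected(self, rng):
        x = rng.standard_normal(8)
        X = np.column_stack([x, x])
        with pytest.raises(np.linalg.LinAlgError):
            gls_fixed_effects(rng.standard_normal(8), X, np.eye(8))


class TestFixedEffectSE:
    def test_single_subject_identity_sigma_is_ols_se(self, rng):
        X = np.column_stack([np.ones(9), rng.standard_normal(9)])
        se = fixed_effect_se([X], [np.eye(9)])
        ref = np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(se, ref, atol=1e-12)

    def test_doubling_sigma2_scales_se_by_sqrt2(self, rng):
        X = np.column_stack([np.ones(9), rng.standard_normal(9)])
        se1 = fixed_effect_se([X], [np.eye(9)])
        se2 = fixed_effect_se([X], [2.0 * np.eye(9)])
        np.testing.assert_allclose(se2, np.sqrt(2.0) * se1, atol=1e-12)


class TestREMLOracle:
    def _tiny_model(self, residual="id"):
        cond = SimulationCondition(3, 4, 0.3, base_seed=23)
        y, z, c, _ = _generate_arrays(cond, TrueParameters(), 0)
        return MultilevelModel.from_arrays(y, z, c, residual=residual), (y, z, c)

    def test_criterion_matches_dense_oracle(self):
        """On an N=3, L=4 panel the criterion at arbitrary parameter points
        must equal the direct dense REML formula to 1e-10."""
        for residual, rho_vals in (("id", [0.0]), ("ar1", [-0.4, 0.0, 0.55])):
            model, (y, z, c) = self._tiny_model(residual)
            for rho in rho_vals:
                for G, s2 in [
                    (np.array([[0.5, 0.15], [0.15, 0.5]]), 1.0),
                    (np.array([[2.0, -0.3], [-0.3, 0.4]]), 0.7),
                    (np.zeros((2, 2)), 1.5),
                ]:
                    resid = ResidualStructure(residual, s2, rho)
                    Sig = [
                        marginal_covariance(
                            G + 1e-12 * np.eye(2), resid, model._Z_blocks[i]
                        )
                        for i in range(3)
                    ]
                    ref = _dense_reml_loglik(model._y_blocks, model._X_blocks, Sig)
                    val = model.loglike_reml(G, s2, rho)
                    assert val == pytest.approx(ref, abs=1e-10)

    def test_optimum_beats_local_grid(self):
        model, _ = self._tiny_model("id")
        res = model.fit()
        G0 = res.cov_re.to_numpy()
        best = res.llf_reml
        for f0 in np.linspace(0.7, 1.3, 10):
            for f1 in np.linspace(0.7, 1.3, 10):
                G = G0 * np.array([[f0, np.sqrt(f0 * f1)], [np.sqrt(f0 * f1), f1]])
                ll = model.loglike_reml(G, res.scale * f0)
                assert ll <= best + 1e-8


class TestREMLProperties:
    def _panel(self, N=20, L=30, rho_bar=0.3, rep=0, seed=31):
        cond = SimulationCondition(N, L, rho_bar, base_seed=seed)
        return _generate_arrays(cond, TrueParameters(), rep)

    def test_shift_invariance(self):
        y, z, c, _ = self._panel()
        r1 = MultilevelModel.from_arrays(y, z, c, residual="id").fit()
        r2 = MultilevelModel.from_arrays(y + 10.0, z, c, residual="id").fit()
        assert r2.fe_params["Intercept"] == pytest.approx(
            r1.fe_params["Intercept"] + 10.0, abs=1e-6
        )
        np.testing.assert_allclose(
            r1.cov_re.to_numpy(), r2.cov_re.to_numpy(), atol=1e-4
        )
        assert r1.scale == pytest.approx(r2.scale, abs=1e-4)
        # the REML criterion itself is exactly invariant to the shift
        m1 = MultilevelModel.from_arrays(y, z, c, residual="id")
        m2 = MultilevelModel.from_arrays(y + 10.0, z, c, residual="id")
        G = np.array([[0.4, 0.1], [0.1, 0.3]])
        assert m1.loglike_reml(G, 1.2) == pytest.approx(
            m2.loglike_reml(G, 1.2), abs=1e-8
        )

    def test_ar1_nests_id(self):
        y, z, c, _ = self._panel(rho_bar=0.6)
        ll_id = MultilevelModel.from_arrays(y, z, c, residual="id").fit().llf_reml
        ll_ar = MultilevelModel.from_arrays(y, z, c, residual="ar1").fit().llf_reml
        assert ll_ar >= ll_id - 1e-6

    def test_ar1_fixed_rho_on_whitened_equals_id(self):
        """Whitening with the TRUE shared rho then fitting ID equals fitting
        AR1 with rho held at the truth, for the fixed effects."""
        rng = np.random.default_rng(7)
        N, L, rho = 15, 25, 0.5
        z = rng.standard_normal((N, L))
        c = rng.standard_normal(N)
        u = rng.multivariate_normal([0, 0], TrueParameters().G, size=N)
        e = np.empty((N, L))
        e[:, 0] = rng.standard_normal(N) / np.sqrt(1 - rho**2)
        for t in range(1, L):
            e[:, t] = rho * e[:, t - 1] + rng.standard_normal(N)
        y = 1 + z + c[:, None] + c[:, None] * z + u[:, [0]] + u[:, [1]] * z + e
        fit_ar = MultilevelModel.from_arrays(y, z, c, residual="ar1").fit(fix_rho=rho)
        ones = np.ones((N, L))
        X = np.stack([ones, z, c[:, None] * ones, c[:, None] * z], axis=2)
        M = np.concatenate([y[:, :, None], X], axis=2)
        Ms = M.copy()
        Ms[:, 1:, :] -= rho * M[:, :-1, :]
        Ms[:, 0, :] *= np.sqrt(1 - rho**2)
        fit_id = MultilevelModel.from_stacked(
            Ms[:, :, 0], Ms[:, :, 1:], Ms[:, :, 1:3], residual="id"
        ).fit()
        np.testing.assert_allclose(
            fit_ar.fe_params.to_numpy(), fit_id.fe_params.to_numpy(), atol=1e-6
        )

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        y, z, c, _ = self._panel(N=25, L=20, rho_bar=0.0, seed=41)
        res = MultilevelModel.from_arrays(y, z, c, residual="id").fit()
        N, L = y.shape
        ones = np.ones((N, L))
        X = np.stack([ones, z, c[:, None] * ones, c[:, None] * z], axis=2)
        m = sm.MixedLM(
            y.ravel(),
            X.reshape(-1, 4),
            groups=np.repeat(np.arange(N), L),
            exog_re=X.reshape(-1, 4)[:, :2],
        ).fit(reml=True)
        np.testing.assert_allclose(res.fe_params.to_numpy(), m.fe_params, atol=1e-4)
        np.testing.assert_allclose(
            res.cov_re.to_numpy(), np.asarray(m.cov_re), atol=1e-3
        )
        assert res.llf_reml == pytest.approx(m.llf, abs=1e-4)

    def test_variance_recovery_no_autocorrelation(self):
        """With rho_bar = 0 and a large panel the REML estimate of the
        random-intercept variance recovers the truth closely."""
        vals = []
        for rep in range(40):
            y, z, c, _ = self._panel(N=100, L=100, rho_bar=0.0, rep=rep, seed=53)
            res = MultilevelModel.from_arrays(y, z, c, residual="id").fit()
            vals.append(res.cov_re.iloc[0, 0])
        assert np.mean(vals) == pytest.approx(0.5, rel=0.05)

    def test_se_calibration_at_rho_zero(self):
        """Model-based SEs of the time-varying effect match the empirical SD
        of its estimates when the model is correctly specified."""
        ses, est = [], []
        for rep in range(300):
            y, z, c, _ = self._panel(N=50, L=50, rho_bar=0.0, rep=rep, seed=61)
            res = MultilevelModel.from_arrays(y, z, c, residual="id").fit()
            ses.append(res.bse["z"])
            est.append(res.fe_params["z"])
        ratio = np.mean(ses) / np.std(est, ddof=1)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_reml_fit_from_dataframe(self, small_panel):
        res = reml_fit(small_panel, "id")
        assert res.fe_params.shape == (4,)
        assert "Residual structure: ID" in res.summary()

    def test_summary_contains_estimates(self):
        y, z, c, _ = self._panel()
        res = MultilevelModel.from_arrays(y, z, c, residual="ar1").fit()
        s = res.summary()
        assert "AR1" in s and "var(u0)" in s and "rho" in s
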