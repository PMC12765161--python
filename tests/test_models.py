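import numpy as np
import pandas as pd
import pytest
from scipy import special

import callrhythm as cr
from callrhythm.errors import FitError
from callrhythm.models import (
    BIN_LEVELS,
    ZipPoissonMixed,
    design_from_bin_counts,
    fit_tempo_model,
)

TRUE_BETA = np.log([5.0, 40.0, 3.0, 8.0, 3.0, 8.0])


def brute_force_marginal_loglik(y, X, offset, groups, params):
    """Fine-trapezoid integration of the ZIP mixed likelihood over the
    random intercept; independent of the quadrature code path."""
    p = X.shape[1]
    beta, zi_logit, log_sigma = params[:p], params[p], params[p + 1]
    pi = 1.0 / (1.0 + np.exp(-zi_logit))
    sigma = np.exp(log_sigma)
    eta0 = X @ beta + offset
    us = np.linspace(-8 * sigma, 8 * sigma, 40001)
    total = 0.0
    for fid in pd.unique(groups):
        sel = groups == fid
        mu = np.exp(eta0[sel][:, None] + us[None, :])
        yy = y[sel][:, None]
        ll = np.where(
            yy == 0,
            np.log(pi + (1 - pi) * np.exp(-mu)),
            np.log(1 - pi) + yy * np.log(mu) - mu - special.gammaln(yy + 1),
        )
        dens = ll.sum(axis=0) - 0.5 * us**2 / sigma**2 - 0.5 * np.log(2 * np.pi * sigma**2)
        total += np.log(np.trapezoid(np.exp(dens), us))
    return total


class TestZipPoissonMixed:
    def test_quadrature_equals_brute_force_integration(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 4, rng=np.random.default_rng(1))
        y, X, off, g, _ = design_from_bin_counts(df)
        model = ZipPoissonMixed(y, X, off, g)
        for shift in (0.0, 0.3, -0.2):
            params = np.concatenate(
                [np.linspace(1.0, 3.5, X.shape[1]) + shift, [special.logit(0.2)], [np.log(0.5)]]
            )
            agh = model.loglik(params)
            brute = brute_force_marginal_loglik(y, X, off, g, params)
            assert agh == pytest.approx(brute, abs=1e-6)

    def test_single_file_no_zi_reduces_to_poisson_glm(self):
        import statsmodels.api as sm

        df = cr.simulate_zip_counts(TRUE_BETA, 0.0, 0.0, 1, rng=np.random.default_rng(2))
        y, X, off, g, _ = design_from_bin_counts(df)
        with pytest.warns(UserWarning, match="fewer than 2 groups"):
            model = ZipPoissonMixed(y, X, off, g, zero_inflation=False)
        fit = model.fit()
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        np.testing.assert_allclose(fit.params[: X.shape[1]], glm.params, atol=1e-6)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_no_zeros_zip_converges_to_plain_poisson_mixed(self):
        rng = np.random.default_rng(3)
        df = cr.simulate_zip_counts(TRUE_BETA + 5.0, 0.0, 0.2, 15, rng=rng)
        assert (df["count"] > 0).all()
        zip_fit = cr.fit_zip_poisson_mixed(df, zero_inflation=True)
        pois_fit = cr.fit_zip_poisson_mixed(df, zero_inflation=False)
        assert zip_fit.diagnostics["pi"] < 1e-3
        np.testing.assert_allclose(
            zip_fit.params[: len(zip_fit.fixed_names)],
            pois_fit.params[: len(pois_fit.fixed_names)],
            atol=2e-3,
        )
        assert zip_fit.loglik == pytest.approx(pois_fit.loglik, abs=1e-3)

    def test_fitted_likelihood_beats_truth_on_simulated_data(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 25, rng=np.random.default_rng(4))
        fit = cr.fit_zip_poisson_mixed(df)
        y, X, off, g, names = design_from_bin_counts(df)
        model = ZipPoissonMixed(y, X, off, g)
        true_params = np.concatenate(
            [[TRUE_BETA[list(BIN_LEVELS).index(n)] for n in names],
             [special.logit(0.2)], [np.log(0.5)]]
        )
        assert fit.loglik >= model.loglik(true_params) - 1e-6

    def test_offset_scaling_shifts_intercepts_leaves_contrasts(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.15, 0.4, 20, rng=np.random.default_rng(5))
        scaled = df.assign(bin_width=df["bin_width"] * 7.0)
        f1 = cr.fit_zip_poisson_mixed(df, seed=0)
        f2 = cr.fit_zip_poisson_mixed(scaled, seed=0)
        k = len(f1.fixed_names)
        np.testing.assert_allclose(f1.params[:k] - f2.params[:k], np.log(7.0), atol=1e-4)
        c1 = cr.posthoc_contrasts(f1)
        c2 = cr.posthoc_contrasts(f2)
        for a, b in zip(c1, c2):
            assert a.estimate == pytest.approx(b.estimate, abs=1e-4)
            assert a.se == pytest.approx(b.se, rel=1e-3)


class TestAgainstGlmmTMB:
    # oracle values from R 4.3.3 / glmmTMB 1.1.9 (Laplace approximation) on
    # the deterministic dataset below:
    #   glmmTMB(count ~ 0 + bin_name + offset(log(bin_width)) + (1|file_id),
    #           ziformula = ~1, family = poisson)
    R_LOGLIK = -143.266806
    R_FIXEF = [3.651058, 5.596112, 3.014512, 4.050709, 2.843465, 3.704852]
    R_SE = [0.231945, 0.153929, 0.329806, 0.246376, 0.379003, 0.267878]
    R_ZI = -1.151223
    R_SIGMA_U = 0.459468

    def _fit(self):
        df = cr.simulate_zip_counts(
            TRUE_BETA + 2.0, 0.25, 0.5, 12, rng=np.random.default_rng(123)
        )
        return cr.fit_zip_poisson_mixed(df)

    def test_matches_independent_mixed_model_fit(self):
        fit = self._fit()
        np.testing.assert_allclose(fit.params[:6], self.R_FIXEF, atol=2e-3)
        np.testing.assert_allclose(
            [fit.se(n) for n in fit.fixed_names], self.R_SE, atol=2e-3
        )
        assert fit.coef("zi_logit") == pytest.approx(self.R_ZI, abs=5e-3)
        assert fit.diagnostics["sigma_u"] == pytest.approx(self.R_SIGMA_U, abs=5e-3)
        # the reference uses a Laplace approximation; exact quadrature sits
        # slightly above it
        assert fit.loglik == pytest.approx(self.R_LOGLIK, abs=0.02)
        assert fit.loglik >= self.R_LOGLIK - 1e-6


class TestLrt:
    def test_identical_fits_give_chi2_zero_p_one(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 10, rng=np.random.default_rng(6))
        fit = cr.fit_zip_poisson_mixed(df)
        chi2, dof, p = cr.lrt_full_vs_null(fit, fit)
        assert chi2 == 0.0 and dof == 0 and p == 1.0

    def test_strong_effect_has_power(self):
        hits = 0
        for rep in range(10):
            df = cr.simulate_zip_counts(
                TRUE_BETA, 0.2, 0.5, 40, rng=np.random.default_rng(100 + rep)
            )
            full = cr.fit_zip_poisson_mixed(df, method="laplace", seed=rep)
            null = cr.fit_zip_poisson_mixed(df, null=True, method="laplace", seed=rep)
            _, _, p = cr.lrt_full_vs_null(full, null)
            hits += p < 0.05
        assert hits >= 9

    def test_mismatched_data_rejected(self):
        df1 = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 10, rng=np.random.default_rng(7))
        df2 = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 13, rng=np.random.default_rng(8))
        with pytest.raises(FitError, match="identical data"):
            cr.lrt_full_vs_null(cr.fit_zip_poisson_mixed(df1), cr.fit_zip_poisson_mixed(df2))


class TestContrasts:
    def test_self_contrast_is_null(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 10, rng=np.random.default_rng(9))
        fit = cr.fit_zip_poisson_mixed(df)
        (con,) = cr.posthoc_contrasts(fit, [("on1:1", "on1:1")])
        assert con.estimate == 0.0 and con.p_value == 1.0

    def test_two_level_poisson_glm_closed_form(self):
        # balanced two-group Poisson counts; contrast = log(lam1/lam2)
        rng = np.random.default_rng(10)
        lam1, lam2, n = 20.0, 5.0, 400
        y = np.concatenate([rng.poisson(lam1, n), rng.poisson(lam2, n)])
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
        with pytest.warns(UserWarning, match="fewer than 2 groups"):
            model = ZipPoissonMixed(y, X, np.zeros(2 * n), np.zeros(2 * n), zero_inflation=False)
        fit = model.fit()
        fit.param_names = ["g1", "g2"]
        (con,) = cr.posthoc_contrasts(fit, [("g1", "g2")])
        m1, m2 = y[:n].mean(), y[n:].mean()
        assert con.estimate == pytest.approx(np.log(m1 / m2), abs=1e-6)
        # closed-form SE of a log-rate difference: sqrt(1/sum1 + 1/sum2)
        assert con.se == pytest.approx(np.sqrt(1 / y[:n].sum() + 1 / y[n:].sum()), rel=1e-3)

    def test_se_matches_finite_difference_hessian(self):
        df = cr.simulate_zip_counts(TRUE_BETA, 0.2, 0.5, 8, rng=np.random.default_rng(11))
        fit = cr.fit_zip_poisson_mixed(df)
        y, X, off, g, names = design_from_bin_counts(df)
        model = ZipPoissonMixed(y, X, off, g)
        # central differences, coarse step, fully independent of approx_hess
        h = 1e-4
        k = len(fit.params)
        H = np.zeros((k, k))
        f0 = -model.loglik(fit.params)
        for i in range(k):
            for j in range(i, k):
                pp = fit.params.copy(); pp[i] += h; pp[j] += h
                pm = fit.params.copy(); pm[i] += h; pm[j] -= h
                mp = fit.params.copy(); mp[i] -= h; mp[j] += h
                mm = fit.params.copy(); mm[i] -= h; mm[j] -= h
                H[i, j] = H[j, i] = (
                    -model.loglik(pp) + model.loglik(pm) + model.loglik(mp) - model.loglik(mm)
                ) / (4 * h * h)
        cov = np.linalg.inv(H)
        for a, b in (("on1:1", "off1:1"),):
            c = np.zeros(k)
            c[names.index(a)] = 1.0
            c[names.index(b)] = -1.0
            se_fd = np.sqrt(c @ cov @ c)
            (con,) = cr.posthoc_contrasts(fit, [(a, b)])
            assert con.se == pytest.approx(se_fd, abs=1e-4)


class TestTempoModel:
    def _tempo_frame(self, corpus):
        from callrhythm.pipeline import tempo_frame
        from callrhythm.rhythm import LEVELS, build_series, compute_tk

        table, _ = corpus
        series = [compute_tk(s) for lev in LEVELS for s in build_series(table, lev)]
        return tempo_frame([s for s in series if not s.flagged])

    def test_zero_jitter_midpoint_pants_give_log_half_contrast(self, clean_corpus):
        tempo = self._tempo_frame(clean_corpus)
        fit, (chi2, dof, p), contrasts = fit_tempo_model(tempo)
        by_pair = {c.pair: c for c in contrasts}
        assert by_pair["series - pulses"].estimate == pytest.approx(np.log(0.5), abs=1e-6)
        assert by_pair["pants - pulses"].estimate == pytest.approx(0.0, abs=1e-6)
        assert dof == 2 and p < 1e-10

    def test_missing_level_raises(self):
        tempo = pd.DataFrame(
            {"section_id": ["a", "a"], "tk_type": ["series", "series"], "t_k": [1.0, 1.1]}
        )
        with pytest.raises(FitError, match="absent"):
            fit_tempo_model(tempo)

    def test_nonpositive_tk_rejected(self):
        tempo = pd.DataFrame(
            {
                "section_id": ["a"] * 3,
                "tk_type": ["series", "pants", "pulses"],
                "t_k": [1.0, -0.1, 2.0],
            }
        )
        with pytest.raises(FitError, match="non-positive"):
            fit_tempo_model(tempo)

    def test_ml_parameter_recovery(self):
        # known fixed effects and variance components, many small sections
        mu = {"series": np.log(1.0), "pants": np.log(2.0), "pulses": np.log(2.0)}
        sd_sec, sd_eps = 0.3, 0.2
        est = []
        for rep in range(25):
            rng = np.random.default_rng(200 + rep)
            rows = []
            for s in range(40):
                u = rng.normal(0, sd_sec)
                for t_type in ("series", "pants", "pulses"):
                    for _ in range(8):
                        rows.append(
                            {
                                "section_id": f"s{s}",
                                "tk_type": t_type,
                                "t_k": float(np.exp(mu[t_type] + u + rng.normal(0, sd_eps))),
                            }
                        )
            fit, _, contrasts = fit_tempo_model(pd.DataFrame(rows))
            by_pair = {c.pair: c for c in contrasts}
            est.append(
                [
                    by_pair["series - pants"].estimate,
                    fit.diagnostics["sigma_section"],
                    fit.diagnostics["sigma_resid"],
                ]
            )
        means = np.mean(est, axis=0)
        assert means[0] == pytest.approx(np.log(1.0) - np.log(2.0), abs=0.03)
        assert means[1] == pytest.approx(sd_sec, abs=0.05)
        assert means[2] == pytest.approx(sd_eps, abs=0.02)
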