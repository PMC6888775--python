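import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from fucusstat.errors import ConvergenceError, InputError
from fucusstat.hurdle import (
    HurdleFit,
    RegressionFit,
    beta_loglik,
    design_matrix,
    fit_beta,
    fit_binomial,
    fit_hurdle,
    predict_hurdle,
    prune_interactions,
    two_way_interactions,
)


def logit(p):
    return np.log(p / (1 - p))


class TestDesignMatrix:
    def test_intercept_only(self):
        df = pd.DataFrame({"salinity": np.arange(5.0)})
        X = design_matrix(df, ["intercept"])
        np.testing.assert_array_equal(X, np.ones((5, 1)))

    def test_interaction_is_elementwise_product(self, rng):
        df = pd.DataFrame(
            {"salinity": rng.normal(size=8), "secchi": rng.normal(size=8)}
        )
        X = design_matrix(df, ["salinity", "secchi", "salinity:secchi"])
        np.testing.assert_allclose(X[:, 2], X[:, 0] * X[:, 1])

    def test_log_exposure_from_exposure(self):
        df = pd.DataFrame({"exposure": [1.0, np.e]})
        X = design_matrix(df, ["log_exposure"])
        np.testing.assert_allclose(X[:, 0], [0.0, 1.0])

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(InputError):
            design_matrix(pd.DataFrame({"exposure": [1.0, 0.0]}), ["log_exposure"])

    def test_existing_log_exposure_column_used(self):
        df = pd.DataFrame({"log_exposure": [2.0, 3.0]})
        np.testing.assert_array_equal(
            design_matrix(df, ["log_exposure"])[:, 0], [2.0, 3.0]
        )

    def test_two_way_interactions_count(self):
        assert len(two_way_interactions(["a", "b", "c", "d", "e"])) == 10


class TestFitBinomial:
    def test_balanced_intercept_is_zero(self):
        y = np.array([1.0] * 63 + [0.0] * 63)
        X = np.ones((126, 1))
        fit = fit_binomial(X, y, ["intercept"])
        assert fit.estimates[0] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_equals_logit_of_proportion(self):
        # closed form: intercept-only MLE is logit(k/n); 106 presences of 126
        y = np.array([1.0] * 106 + [0.0] * 20)
        fit = fit_binomial(np.ones((126, 1)), y, ["intercept"])
        assert fit.estimates[0] == pytest.approx(logit(106 / 126), abs=1e-8)
        assert fit.n == 126

    def test_all_ones_is_separation_error(self):
        with pytest.raises(ConvergenceError):
            fit_binomial(np.ones((20, 1)), np.ones(20), ["intercept"])

    def test_complete_separation_raises(self):
        x = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(20), x])
        with pytest.raises(ConvergenceError):
            fit_binomial(X, y, ["intercept", "x"])

    def test_matches_grid_search_oracle(self, rng):
        # oracle: dense 2-d grid over (b0, b1) maximizing the literal loglik
        x = rng.normal(size=30)
        y = (rng.uniform(size=30) < special.expit(0.3 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(30), x])
        fit = fit_binomial(X, y, ["intercept", "x"])

        def ll(b0, b1):
            p = special.expit(b0 + b1 * x)
            return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        grid = np.linspace(-3, 3, 241)
        best = max(itertools.product(grid, grid), key=lambda b: ll(*b))
        assert fit.estimates[0] == pytest.approx(best[0], abs=1.5e-2)
        assert fit.estimates[1] == pytest.approx(best[1], abs=1.5e-2)
        # and the likelihood at the MLE beats the grid optimum
        assert ll(*fit.estimates) >= ll(*best) - 1e-9

    def test_loglik_trace_is_ascending(self, rng):
        x = rng.normal(size=50)
        y = (rng.uniform(size=50) < special.expit(x)).astype(float)
        fit = fit_binomial(np.column_stack([np.ones(50), x]), y, ["intercept", "x"])
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_wald_outputs_consistent(self, rng):
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < special.expit(0.5 * x)).astype(float)
        fit = fit_binomial(np.column_stack([np.ones(80), x]), y, ["intercept", "x"])
        np.testing.assert_allclose(fit.stat_values, fit.estimates / fit.std_errors)
        np.testing.assert_allclose(
            fit.p_values, 2 * stats.norm.sf(np.abs(fit.stat_values))
        )

    def test_non_binary_response_rejected(self):
        with pytest.raises(InputError):
            fit_binomial(np.ones((4, 1)), np.array([0.0, 0.5, 1.0, 1.0]), ["i"])


class TestFitBeta:
    def test_symmetric_rates_zero_intercept(self):
        rates = np.array([0.3, 0.7, 0.4, 0.6, 0.45, 0.55, 0.5 - 1e-9, 0.5 + 1e-9])
        fit = fit_beta(np.ones((len(rates), 1)), rates, ["intercept"])
        assert fit.estimates[0] == pytest.approx(0.0, abs=1e-6)

    def test_boundary_rates_rejected(self):
        with pytest.raises(InputError):
            fit_beta(np.ones((3, 1)), np.array([0.0, 0.5, 0.7]), ["i"])
        with pytest.raises(InputError):
            fit_beta(np.ones((3, 1)), np.array([0.2, 0.5, 1.0]), ["i"])

    def test_matches_grid_search_oracle_2param(self, rng):
        # oracle: dense grid over (intercept, log phi), independent density
        # evaluation through scipy.stats.beta.logpdf
        y = rng.beta(2.0, 3.0, size=25)
        X = np.ones((25, 1))
        fit = fit_beta(X, y, ["intercept"])

        def ll(b0, logphi):
            mu = special.expit(b0)
            phi = np.exp(logphi)
            return float(
                np.sum(stats.beta.logpdf(y, mu * phi, (1 - mu) * phi))
            )

        b0_grid = np.linspace(-2, 2, 321)
        lp_grid = np.linspace(-1, 4, 321)
        best = max(itertools.product(b0_grid, lp_grid), key=lambda b: ll(*b))
        assert fit.estimates[0] == pytest.approx(best[0], abs=1.5e-2)
        assert np.log(fit.phi) == pytest.approx(best[1], abs=1.6e-2)
        assert ll(fit.estimates[0], np.log(fit.phi)) >= ll(*best) - 1e-9

    def test_loglik_equals_independent_formula(self, rng):
        y = rng.beta(2.0, 2.0, size=15)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        params = np.array([0.2, -0.3, np.log(7.0)])
        mu = special.expit(X @ params[:2])
        oracle = float(np.sum(stats.beta.logpdf(y, mu * 7.0, (1 - mu) * 7.0)))
        assert beta_loglik(params, X, y) == pytest.approx(oracle, rel=1e-10)

    def test_loglik_trace_is_ascending(self, rng):
        x = rng.normal(size=60)
        mu = special.expit(0.4 + 0.6 * x)
        y = rng.beta(mu * 15, (1 - mu) * 15)
        fit = fit_beta(np.column_stack([np.ones(60), x]), y, ["intercept", "x"])
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_covariate_shift_changes_only_intercept(self, rng):
        # main-effects model: x -> x + c shifts the intercept by -c*beta
        x = rng.normal(size=120)
        mu = special.expit(0.2 + 0.5 * x)
        y = rng.beta(mu * 20, (1 - mu) * 20)
        X1 = np.column_stack([np.ones(120), x])
        X2 = np.column_stack([np.ones(120), x + 5.0])
        f1 = fit_beta(X1, y, ["intercept", "x"])
        f2 = fit_beta(X2, y, ["intercept", "x"])
        assert f2.estimates[1] == pytest.approx(f1.estimates[1], abs=1e-5)
        assert f2.estimates[0] == pytest.approx(
            f1.estimates[0] - 5.0 * f1.estimates[1], abs=1e-4
        )
        assert f2.phi == pytest.approx(f1.phi, rel=1e-4)

    def test_phi_recovered_roughly(self, rng):
        y = rng.beta(0.5 * 40, 0.5 * 40, size=4000)
        fit = fit_beta(np.ones((4000, 1)), y, ["intercept"])
        assert fit.phi == pytest.approx(40.0, rel=0.15)


class TestPruneInteractions:
    def _simulate(self, rng, n=300, interaction=0.0):
        df = pd.DataFrame(
            {"salinity": rng.uniform(2, 6, n), "secchi": rng.uniform(1, 7, n)}
        )
        eta = (
            -1.0 + 0.3 * df["salinity"] + 0.2 * df["secchi"]
            + interaction * df["salinity"] * df["secchi"]
        )
        mu = special.expit(eta)
        y = rng.beta(mu * 60, (1 - mu) * 60)
        return df, np.asarray(y)

    def test_null_interactions_all_dropped(self, rng):
        df, y = self._simulate(rng, interaction=0.0)
        terms = ["intercept", "salinity", "secchi", "salinity:secchi"]
        fit, final, ledger = prune_interactions(fit_beta, df, y, terms)
        assert final == ["intercept", "salinity", "secchi"]
        assert [e["term"] for e in ledger] == ["salinity:secchi"]

    def test_strong_interaction_survives(self, rng):
        df, y = self._simulate(rng, interaction=-0.2)
        terms = ["intercept", "salinity", "secchi", "salinity:secchi"]
        fit, final, ledger = prune_interactions(fit_beta, df, y, terms)
        assert "salinity:secchi" in final

    def test_main_effects_never_dropped(self, rng):
        # salinity truly has no effect, but only interactions are candidates
        df = pd.DataFrame(
            {"salinity": rng.uniform(2, 6, 200), "secchi": rng.uniform(1, 7, 200)}
        )
        mu = special.expit(0.1 * df["secchi"] - 0.5)
        y = np.asarray(rng.beta(mu * 30, (1 - mu) * 30))
        terms = ["intercept", "salinity", "secchi", "salinity:secchi"]
        _, final, _ = prune_interactions(fit_beta, df, y, terms)
        assert {"intercept", "salinity", "secchi"} <= set(final)

    def test_one_drop_per_step_largest_p_first(self, rng):
        df, y = self._simulate(rng, interaction=0.0)
        df["ntot"] = rng.uniform(200, 500, len(df))
        terms = [
            "intercept", "salinity", "secchi", "ntot",
            "salinity:secchi", "salinity:ntot", "secchi:ntot",
        ]
        _, _, ledger = prune_interactions(fit_beta, df, y, terms)
        assert [e["step"] for e in ledger] == list(range(1, len(ledger) + 1))


class TestFitHurdle:
    def _zone_data(self, rng, n=126, n_zero=20):
        df = pd.DataFrame(
            {
                "salinity": rng.uniform(2, 6.5, n),
                "exposure": rng.uniform(1e4, 3e5, n),
                "secchi": rng.uniform(3, 6, n),
                "ntot": rng.uniform(250, 550, n),
                "ptot": rng.uniform(10, 40, n),
            }
        )
        mu = special.expit(-1.0 + 0.3 * df["salinity"])
        rates = np.asarray(rng.beta(mu * 20, (1 - mu) * 20))
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        rates[zero_idx] = 0.0
        return df, rates

    def test_sample_split_counts(self, rng):
        df, rates = self._zone_data(rng)
        fit = fit_hurdle(df, rates)
        assert fit.positive_part.n == int((rates > 0).sum()) == 106
        assert fit.binomial_part.n == 126
        assert fit.positive_part.family == "beta"
        assert fit.binomial_part.family == "binomial"

    def test_percent_scale_invariance(self, rng):
        df, rates = self._zone_data(rng)
        f1 = fit_hurdle(df, rates)
        f2 = fit_hurdle(df, rates * 100.0)
        np.testing.assert_allclose(
            f1.positive_part.estimates, f2.positive_part.estimates, rtol=1e-6
        )
        np.testing.assert_allclose(
            f1.binomial_part.estimates, f2.binomial_part.estimates, rtol=1e-6
        )

    def test_zero_free_data_flags_binomial_degenerate(self, rng):
        df, rates = self._zone_data(rng, n_zero=0)
        fit = fit_hurdle(df, rates)
        assert not fit.binomial_part.converged
        assert np.all(np.isnan(fit.binomial_part.estimates))
        assert fit.positive_part.converged

    def test_too_few_positive_zones(self, rng):
        df, rates = self._zone_data(rng, n=20, n_zero=15)
        with pytest.raises(InputError):
            fit_hurdle(df, rates)

    def test_binomial_terms_are_mains_plus_surviving_interactions(self, rng):
        df, rates = self._zone_data(rng)
        fit = fit_hurdle(df, rates)
        kept = [t for t in fit.positive_part.terms if ":" in t]
        expected = ["intercept", "salinity", "log_exposure", "secchi",
                    "ntot", "ptot", *kept]
        assert fit.binomial_part.terms == expected

    def test_rates_out_of_range_rejected(self, rng):
        df, _ = self._zone_data(rng, n=30, n_zero=0)
        with pytest.raises(InputError):
            fit_hurdle(df, np.full(30, -0.1))


class TestPredictHurdle:
    def _manual_fit(self, pos_coefs, bin_coefs, terms):
        def mk(coefs, family):
            k = len(terms)
            return RegressionFit(
                family=family, link="logit", terms=list(terms),
                estimates=np.asarray(coefs, dtype=float),
                std_errors=np.ones(k), stat_values=np.ones(k),
                p_values=np.ones(k), stat_name="z", log_likelihood=0.0,
                n=10, converged=True, phi=10.0 if family == "beta" else None,
            )

        return HurdleFit(
            positive_part=mk(pos_coefs, "beta"),
            binomial_part=mk(bin_coefs, "binomial"),
            dropped_terms=[],
        )

    def test_hand_computed_product(self):
        terms = ["intercept", "salinity"]
        fit = self._manual_fit([0.5, 0.2], [-0.3, 0.4], terms)
        df = pd.DataFrame({"salinity": [2.0, 4.0, 6.0]})
        out = predict_hurdle(fit, df)
        for i, s in enumerate([2.0, 4.0, 6.0]):
            p = special.expit(-0.3 + 0.4 * s)
            mu = special.expit(0.5 + 0.2 * s)
            assert out[i] == pytest.approx(p * mu, rel=1e-12)

    def test_certain_presence_returns_beta_mean(self):
        terms = ["intercept"]
        fit = self._manual_fit([0.7], [40.0], terms)  # p = expit(40) ~ 1
        out = predict_hurdle(fit, pd.DataFrame(index=range(3)))
        np.testing.assert_allclose(out, special.expit(0.7), rtol=1e-10)

    def test_certain_absence_returns_zero(self):
        fit = self._manual_fit([0.7], [-40.0], ["intercept"])
        out = predict_hurdle(fit, pd.DataFrame(index=range(3)))
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_extrapolation_warns(self, rng):
        df = pd.DataFrame(
            {
                "salinity": rng.uniform(2, 6, 80),
                "exposure": rng.uniform(1e4, 1e5, 80),
                "secchi": rng.uniform(3, 6, 80),
                "ntot": rng.uniform(250, 550, 80),
                "ptot": rng.uniform(10, 40, 80),
            }
        )
        mu = special.expit(-0.5 + 0.2 * df["salinity"])
        rates = np.asarray(rng.beta(mu * 20, (1 - mu) * 20))
        rates[:15] = 0.0
        fit = fit_hurdle(df, rates)
        new = df.head(3).copy()
        new.loc[new.index[0], "salinity"] = 60.0
        with pytest.warns(UserWarning, match="outside the design support"):
            predict_hurdle(fit, new)

    def test_nonconverged_fit_rejected(self):
        fit = self._manual_fit([0.7], [0.0], ["intercept"])
        fit.binomial_part.converged = False
        with pytest.raises(ConvergenceError):
            predict_hurdle(fit, pd.DataFrame(index=range(2)))
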