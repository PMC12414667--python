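"""Association engine: closed-form and brute-force oracles for OLS, exact
enumeration for Fisher, penalized-likelihood oracle for Firth, and the
inverse-variance pooling identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from adh1score import association as assoc


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOlsCarrierBeta:
    def test_no_covariates_equals_group_mean_difference(self):
        res = assoc.ols_carrier_beta([2.0, 2.2, 2.4, 1.6], [0, 0, 0, 1])
        assert res.beta == pytest.approx(-0.6, abs=1e-12)

    def test_constant_response_gives_zero_beta(self):
        res = assoc.ols_carrier_beta([2.0] * 6, [0, 1, 0, 0, 1, 0])
        assert res.beta == 0.0 and res.p_value == 1.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 80)
        carrier = np.zeros(80)
        carrier[3] = 1
        cov = rng.normal(0, 1, (80, 3))
        res = assoc.ols_carrier_beta(y, carrier, cov)
        X = np.column_stack([np.ones(80), carrier, cov])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res.beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_collinear_covariate_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 40)
        carrier = (rng.random(40) < 0.2).astype(float)
        carrier[0] = 1
        cov = np.column_stack([rng.normal(0, 1, 40)])
        cov = np.column_stack([cov, 2 * cov[:, 0]])     # exact collinearity
        with caplog.at_level("WARNING"):
            res = assoc.ols_carrier_beta(y, carrier, cov)
        assert np.isfinite(res.beta)
        assert any("collinear" in r.message for r in caplog.records)

    def test_no_carriers_rejected(self):
        with pytest.raises(ValueError):
            assoc.ols_carrier_beta([1.0, 2.0], [0, 0])

    def test_zero_residual_dof_rejected(self):
        with pytest.raises(ValueError):
            assoc.ols_carrier_beta([1.0, 2.0], [0, 1])


class TestCarrierOLSFastPath:
    def test_identical_to_statsmodels_refit(self):
        """The shared-projection path must reproduce the full OLS carrier
        coefficient, its standard error, and p-value to 1e-10."""
        rng = np.random.default_rng(3)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(0, 1, (n, 4))])
        y = X @ rng.normal(0, 0.5, 5) + rng.normal(0, 1, n)
        fast = assoc.CarrierOLS(y, X)
        for k in (1, 2, 7, 30):
            idx = rng.choice(n, size=k, replace=False)
            carrier = np.zeros(n)
            carrier[idx] = 1.0
            ref = assoc.ols_carrier_beta(y, carrier, X[:, 1:])
            got = fast.carrier_beta(idx)
            assert got[0] == pytest.approx(ref.beta, abs=1e-10)
            assert got[1] == pytest.approx(ref.se, abs=1e-10)
            assert got[2] == pytest.approx(ref.p_value, abs=1e-10)


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided exact p by direct enumeration: sum hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed table."""
    n1, N, K = a + b, a + b + c + d, a + c
    rv = stats.hypergeom(N, K, n1)
    support = np.arange(max(0, n1 + K - N), min(n1, K) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestFisher:
    def test_symmetric_table(self):
        res = assoc.fisher_carrier_enrichment(5, 5, 5, 5)
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_infinite_odds_ratio_table(self):
        res = assoc.fisher_carrier_enrichment(1, 0, 1, 99)
        assert res.odds_ratio == np.inf
        assert res.p_value == pytest.approx(fisher_enumeration_oracle(1, 0, 1, 99),
                                            abs=1e-12)
        assert res.p_value == pytest.approx(0.0198019801980198, abs=1e-12)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        if a + b == 0 or a + b + c + d == 0:
            return
        res = assoc.fisher_carrier_enrichment(a, b, c, d)
        assert res.p_value == pytest.approx(fisher_enumeration_oracle(a, b, c, d),
                                            abs=1e-12)

    @pytest.mark.parametrize("table", [(0, 0, 0, 0), (-1, 2, 3, 4), (1.5, 2, 3, 4)])
    def test_invalid_tables_rejected(self, table):
        with pytest.raises(ValueError):
            assoc.fisher_carrier_enrichment(*table)

    def test_display_odds_ratio_finite_under_zero_cells(self):
        assert np.isfinite(assoc.display_odds_ratio(1, 0, 0, 99))


# ---------------------------------------------------------------------------
# Firth
# ---------------------------------------------------------------------------

def _toy_separated():
    # complete separation with comfortably more than 10 events per variable
    y = np.r_[np.ones(25), np.zeros(45)]
    carrier = np.r_[np.ones(25), np.zeros(45)]
    return y, carrier


class TestFirth:
    def test_finite_beta_under_complete_separation(self):
        y, carrier = _toy_separated()
        res = assoc.firth_logistic(y, carrier)
        assert np.isfinite(res.beta) and res.beta > 0
        assert res.p_value < 1e-6

    def test_near_null_on_balanced_data(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 400).astype(float)
        carrier = rng.integers(0, 2, 400).astype(float)
        res = assoc.firth_logistic(y, carrier)
        assert abs(res.beta) < 0.5
        assert res.p_value > 0.01

    def test_p_values_roughly_uniform_under_null(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            y = rng.integers(0, 2, 200).astype(float)
            carrier = rng.integers(0, 2, 200).astype(float)
            ps.append(assoc.firth_logistic(y, carrier).p_value)
        assert 0.25 < np.mean(ps) < 0.75
        assert np.mean(np.array(ps) < 0.05) < 0.25

    def test_matches_penalized_likelihood_maximizer(self):
        """Independent oracle: numerically maximize the Jeffreys-penalized
        likelihood and compare the carrier coefficient to 1e-6."""
        rng = np.random.default_rng(6)
        n = 120
        carrier = (rng.random(n) < 0.3).astype(float)
        logit = -0.5 + 1.2 * carrier
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        res = assoc.firth_logistic(y, carrier)
        X = np.column_stack([np.ones(n), carrier])

        def neg_pll(b):
            eta = X @ b
            mu = 1 / (1 + np.exp(-eta))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = y @ np.log(mu) + (1 - y) @ np.log(1 - mu)
            info = (X * (mu * (1 - mu))[:, None]).T @ X
            return -(ll + 0.5 * np.linalg.slogdet(info)[1])

        opt = optimize.minimize(neg_pll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert res.beta == pytest.approx(opt.x[1], abs=1e-6)

    def test_events_per_variable_precondition_enforced(self):
        y = np.r_[np.ones(5), np.zeros(50)]
        carrier = np.r_[np.ones(3), np.zeros(52)]
        with pytest.raises(ValueError, match="events"):
            assoc.firth_logistic(y, carrier)


@pytest.mark.parametrize("n_events,n_vars,expected", [
    (3, 12, ["fisher"]),
    (200, 12, ["fisher", "firth"]),
    (0, 5, ["fisher"]),
])
def test_select_test_rule(n_events, n_vars, expected):
    assert assoc.select_test(n_events, n_vars) == expected


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def _res(beta, se, stratum="s"):
    return assoc.AssociationResult(None, stratum, "calcium", "quantitative",
                                   beta=beta, se=se, p_value=0.5, method="ols")


class TestMeta:
    def test_single_stratum_identity(self):
        m = assoc.meta_fixed_effect([_res(-0.2, 0.1)])
        assert m.beta == pytest.approx(-0.2) and m.se == pytest.approx(0.1)

    def test_two_equal_strata(self):
        m = assoc.meta_fixed_effect([_res(-0.2, 0.1, "a"), _res(-0.2, 0.1, "b")])
        assert m.beta == pytest.approx(-0.2)
        assert m.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    def test_opposite_betas_cancel(self):
        m = assoc.meta_fixed_effect([_res(0.3, 0.05, "a"), _res(-0.3, 0.05, "b")])
        assert m.beta == pytest.approx(0.0, abs=1e-15)
        assert m.p_value == pytest.approx(1.0)

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 3)),
                    min_size=1, max_size=6))
    def test_pooled_se_never_exceeds_smallest_component(self, pairs):
        results = [_res(b, s, str(i)) for i, (b, s) in enumerate(pairs)]
        m = assoc.meta_fixed_effect(results)
        assert m.se <= min(s for _, s in pairs) + 1e-12

    def test_all_unusable_rejected(self):
        with pytest.raises(ValueError):
            assoc.meta_fixed_effect([_res(np.inf, 0.1)])

    def test_stouffer_concordant_signals_reinforce(self):
        p_both = assoc.stouffer_meta([0.04, 0.04], [1, 1])
        assert p_both < 0.04
        p_opposed = assoc.stouffer_meta([0.04, 0.04], [1, -1])
        assert p_opposed == pytest.approx(1.0)
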