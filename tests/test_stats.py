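"""Statistics layer: sandwich SEs, Tukey ladder, FDR, mediation, moderation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sleepmicro as sm
from sleepmicro.stats import apply_power


def _toy_table(seed=0, n=12):
    """Fixed small table with heteroskedastic noise."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(-1, 2, n)
    x2 = rng.standard_normal(n)
    y = 1.0 + 2.0 * x1 - 0.5 * x2 + np.abs(x1) * rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


def sandwich_oracle(X, y, flavor="HC1"):
    """Independent matrix-arithmetic sandwich covariance."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    e = y - X @ beta
    n, k = X.shape
    meat = X.T @ np.diag(e**2) @ X
    cov = XtX_inv @ meat @ XtX_inv
    if flavor == "HC1":
        cov *= n / (n - k)
    return beta, cov


class TestRobustGLM:
    def test_sandwich_matches_matrix_oracle(self):
        table = _toy_table()
        res = sm.fit_glm_robust(table, "y", ["x1", "x2"], covariates=())
        X = np.column_stack([np.ones(len(table)), table["x1"], table["x2"]])
        beta, cov = sandwich_oracle(X, table["y"].to_numpy())
        got = np.array([res.term(t).coef for t in ("const", "x1", "x2")])
        got_se = np.array([res.term(t).robust_se for t in ("const", "x1", "x2")])
        assert np.max(np.abs(got - beta)) < 1e-10
        assert np.max(np.abs(got_se - np.sqrt(np.diag(cov)))) < 1e-10

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC3"])
    def test_other_sandwich_flavors_exposed(self, flavor):
        table = _toy_table(1)
        res = sm.fit_glm_robust(table, "y", ["x1"], covariates=("x2",),
                                cov_type=flavor)
        assert res.cov_type == flavor
        assert res.term("x1").robust_se > 0

    def test_exact_linear_fit_zero_robust_se(self):
        table = pd.DataFrame({"x": np.arange(10.0)})
        table["y"] = 3.0 + 2.0 * table["x"]
        res = sm.fit_glm_robust(table, "y", ["x"], covariates=())
        assert res.term("x").coef == pytest.approx(2.0, abs=1e-10)
        assert res.term("x").robust_se == pytest.approx(0.0, abs=1e-8)

    def test_ci_is_beta_plus_minus_1_96_se(self):
        res = sm.fit_glm_robust(_toy_table(2), "y", ["x1"], covariates=("x2",))
        t = res.term("x1")
        assert t.ci_low == pytest.approx(t.coef - 1.96 * t.robust_se, abs=1e-4)
        assert t.ci_high == pytest.approx(t.coef + 1.96 * t.robust_se, abs=1e-4)

    def test_duplicated_predictor_raises_naming_terms(self):
        table = _toy_table(3)
        table["x1_copy"] = table["x1"]
        with pytest.raises(ValueError, match="collinear.*x1"):
            sm.fit_glm_robust(table, "y", ["x1", "x1_copy"], covariates=())

    def test_ten_per_parameter_rule_warns(self):
        with pytest.warns(UserWarning, match="per-parameter"):
            sm.fit_glm_robust(_toy_table(4), "y", ["x1", "x2"], covariates=())

    def test_vif_unit_for_orthogonal_large_for_collinear(self):
        rng = np.random.default_rng(5)
        n = 300
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        t = pd.DataFrame({"a": a, "b": b, "c": a + 0.05 * rng.standard_normal(n)})
        t["y"] = a + b + rng.standard_normal(n)
        res = sm.fit_glm_robust(t, "y", ["a", "b"], covariates=())
        assert res.vif["a"] == pytest.approx(1.0, abs=0.1)
        res2 = sm.fit_glm_robust(t, "y", ["a", "c"], covariates=())
        assert res2.vif["a"] > 2
        assert "VIF" in res.summary()

    def test_binomial_family(self):
        rng = np.random.default_rng(6)
        n = 800
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.3 + 1.2 * x)))
        t = pd.DataFrame({"x": x, "y": (rng.uniform(size=n) < p).astype(float)})
        res = sm.fit_glm_robust(t, "y", ["x"], covariates=(), family="binomial")
        assert res.term("x").coef == pytest.approx(1.2, abs=0.3)


class TestTukeyLadder:
    def test_chi_square_like_selects_sqrt(self):
        rng = np.random.default_rng(42)
        y = rng.standard_normal(2000) ** 2
        assert sm.tukey_ladder_select(y).lam == 0.5

    def test_normal_selects_identity(self):
        rng = np.random.default_rng(42)
        y = 50 + 5 * rng.standard_normal(2000)
        res = sm.tukey_ladder_select(y)
        assert res.lam == 1.0
        assert res.name == "identity"

    def test_zero_values_skip_log_rung_with_warning(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([[0.0], rng.uniform(1, 2, 100)])
        with pytest.warns(UserWarning, match="skipping ladder rung"):
            res = sm.tukey_ladder_select(y)
        assert 0.0 not in set(res.table["lambda"])

    def test_apply_power_guards_domain(self):
        with pytest.raises(ValueError, match="strictly positive"):
            apply_power(np.array([0.0, 1.0]), 0.0)
        with pytest.raises(ValueError, match="strictly positive"):
            apply_power(np.array([-1.0, 1.0]), -1.0)

    def test_negative_rungs_are_monotone(self):
        y = np.array([1.0, 2.0, 5.0])
        for lam in (-2.0, -1.0, -0.5, 0.0, 0.5, 2.0):
            t = apply_power(y, lam)
            assert np.all(np.diff(t) > 0)


def _bh_enumerate(p, q):
    """Exhaustive step-up: largest i with p(i) <= i*q/m, reject 1..i."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    prev = 1.0
    for i in range(m, 0, -1):
        prev = min(prev, m * p[order[i - 1]] / i)
        adj[order[i - 1]] = prev
    return reject, adj


class TestBHFDR:
    def test_all_ones_no_rejection(self):
        rej, adj = sm.bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()
        assert np.all(adj == 1.0)

    def test_stepup_thresholds_all_rejected(self):
        # thresholds i*q/m = 0.0125, 0.025, 0.0375, 0.05
        rej, _ = sm.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_single_p(self):
        rej, adj = sm.bh_fdr([0.04], q=0.05)
        assert rej[0] and adj[0] == pytest.approx(0.04)

    def test_empty_input(self):
        rej, adj = sm.bh_fdr([])
        assert rej.size == 0 and adj.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sm.bh_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=20),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_exhaustive_enumeration(self, pvals, q):
        rej, adj = sm.bh_fdr(pvals, q)
        want_rej, want_adj = _bh_enumerate(pvals, q)
        assert np.array_equal(rej, want_rej)
        np.testing.assert_allclose(adj, want_adj, atol=1e-12)


class TestDeclineOdds:
    def test_parameter_recovery(self):
        """Generator logit(P) = -0.5 - 1*sp_density: OR per unit ~ e^-1."""
        t = sm.generate_cohort(sm.CohortConfig(n=5000, seed=3,
                                               decline_beta=-1.0))
        res = sm.mmse_decline_odds(t, "sp_density")
        assert res.odds_ratio == pytest.approx(np.exp(-1.0), rel=0.10)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert "OR" in res.summary()

    def test_null_coverage(self):
        """Under no metric effect the 95% CI covers OR=1 at ~95%."""
        cover = 0
        n_seeds = 200
        for s in range(n_seeds):
            t = sm.generate_cohort(sm.CohortConfig(n=400, seed=s,
                                                   decline_beta=0.0))
            r = sm.mmse_decline_odds(t, "sp_density")
            cover += r.ci_low <= 1.0 <= r.ci_high
        assert cover / n_seeds == pytest.approx(0.95, abs=0.04)

    def test_constant_indicator_errors(self):
        t = sm.generate_cohort(sm.CohortConfig(n=50, seed=0))
        t["mmse_36"] = t["mmse_0"] - 1.0  # everyone declines
        with pytest.raises(ValueError, match="constant"):
            sm.mmse_decline_odds(t, "sp_density")

    def test_perfect_separation_errors(self):
        t = sm.generate_cohort(sm.CohortConfig(n=200, seed=1))
        metric = np.linspace(-1, 1, len(t))
        t["sep"] = metric
        t["mmse_36"] = np.where(metric > 0, t["mmse_0"] - 2, t["mmse_0"] + 2)
        with pytest.raises(ValueError, match="separat"):
            sm.mmse_decline_odds(t, "sep")


class TestMediation:
    def test_null_a_path(self):
        t = sm.generate_cohort(sm.CohortConfig(n=3000, b_path=0.4,
                                               c_prime=0.3, seed=4))
        res = sm.sobel_goodman(t, "exposure", "mediator", "outcome")
        assert res.indirect == pytest.approx(0.0, abs=0.03)
        assert abs(res.sobel_z) < 3
        assert res.prop_mediated == pytest.approx(0.0, abs=0.1)

    def test_planted_paths_and_proportion(self):
        t = sm.generate_cohort(sm.CohortConfig(n=5000, a_path=0.5, b_path=0.4,
                                               c_prime=0.2, seed=3))
        res = sm.sobel_goodman(t, "exposure", "mediator", "outcome")
        assert res.a == pytest.approx(0.5, abs=0.05)
        assert res.b == pytest.approx(0.4, abs=0.05)
        assert res.c_prime == pytest.approx(0.2, abs=0.05)
        assert res.prop_mediated == pytest.approx(0.5, abs=0.05)
        assert res.sobel_p < 1e-6
        assert res.goodman2_z >= res.sobel_z >= res.goodman1_z > 0

    def test_mediation_identity_exact(self):
        for seed in range(5):
            t = sm.generate_cohort(sm.CohortConfig(
                n=200, a_path=0.4, b_path=0.3, c_prime=0.1, seed=seed))
            res = sm.sobel_goodman(t, "exposure", "mediator", "outcome",
                                   covariates=("age", "sex"))
            assert abs(res.c - (res.c_prime + res.indirect)) < 1e-8

    def test_suppression_flagged(self):
        t = sm.generate_cohort(sm.CohortConfig(n=5000, a_path=0.6,
                                               b_path=-0.3, c_prime=0.5,
                                               seed=6))
        res = sm.sobel_goodman(t, "exposure", "mediator", "outcome")
        assert res.suppression
        assert res.prop_mediated < 0
        assert "suppression" in res.summary()

    def test_zero_variance_mediator_errors(self):
        t = sm.generate_cohort(sm.CohortConfig(n=100, seed=0))
        t["mediator"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            sm.sobel_goodman(t, "exposure", "mediator", "outcome")


class TestModeration:
    def test_planted_interaction_recovered(self):
        t = sm.generate_cohort(sm.CohortConfig(n=5000, gamma=0.5, seed=3))
        res = sm.moderation(t, "exposure", "moderator", "outcome",
                            covariates=())
        assert res.gamma == pytest.approx(0.5, abs=0.05)
        assert res.p < 1e-10
        assert len(res.simple_slopes) == 3
        assert "simple slopes" in res.summary()

    def test_simple_slopes_increase_with_positive_gamma(self):
        t = sm.generate_cohort(sm.CohortConfig(n=5000, c_prime=0.2,
                                               gamma=0.5, seed=3))
        res = sm.moderation(t, "exposure", "moderator", "outcome",
                            covariates=())
        slopes = res.simple_slopes["slope"].to_numpy()
        assert np.all(np.diff(slopes) > 0)

    def test_constant_moderator_rank_deficient(self):
        t = sm.generate_cohort(sm.CohortConfig(n=200, seed=0))
        t["moderator"] = 2.0
        with pytest.raises(ValueError, match="collinear"):
            sm.moderation(t, "exposure", "moderator", "outcome",
                          covariates=())


class TestBattery:
    def test_planted_metric_outcome_pair_detected_and_nulls_quiet(self):
        """With only the spindle-density -> cognition path planted, the MMSE
        cells light up and the biomarker grid stays null."""
        t = sm.generate_cohort(sm.CohortConfig(n=4000, b_path=0.8, seed=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = sm.run_full_battery(t)
        a = rep.associations.set_index(["outcome", "metric"])
        assert a.loc[("mmse_36", "sp_density"), "significant"]
        bio = rep.associations[rep.associations["family"] == "biomarker"]
        assert bio["significant"].mean() < 0.1
        assert "FDR" in rep.summary()

    def test_single_participant_skips_all_fits_with_warnings(self):
        t = sm.generate_cohort(sm.CohortConfig(n=1, seed=0))
        rep = sm.run_full_battery(t)
        assert rep.associations.empty
        assert rep.warnings
        assert all("skipped" in w for w in rep.warnings)

    def test_missing_columns_listed(self):
        t = sm.generate_cohort(sm.CohortConfig(n=50, seed=0))
        with pytest.raises(KeyError, match="abeta42"):
            sm.run_full_battery(t.drop(columns=["abeta42", "sp_density"]))

    def test_skewed_ratio_outcome_gets_transformed(self):
        t = sm.generate_cohort(sm.CohortConfig(n=500, skew=2.5, seed=2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = sm.run_full_battery(t)
        cells = rep.associations[
            rep.associations["outcome"] == "ratio_ptau_abeta42"]
        assert (cells["transform"] != "identity").all()
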