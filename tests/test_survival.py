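"""KM / log-rank / reverse-KM estimators and the Cox fitters."""

import numpy as np
import pytest

from mirsurv.survival import (ConvergenceError, SurvivalOutcome, breslow_loglik,
                              compute_lambda_max, fit_cox, fit_penalized_cox,
                              km_estimate, logrank_test, penalized_cox_path,
                              prognostic_index, reverse_km_median_followup,
                              select_lambda_cv)

from conftest import random_survival


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        out = SurvivalOutcome(np.arange(1.0, 6.0), np.zeros(5, dtype=int))
        km = km_estimate(out)["all"]
        assert np.allclose(km.survival, 1.0)
        assert not km.median_reached

    def test_three_events_no_censoring_closed_form(self):
        out = SurvivalOutcome(np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int))
        km = km_estimate(out)["all"]
        steps = km.survival[np.isin(km.times, [1, 2, 3])]
        assert np.allclose(steps, [2 / 3, 1 / 3, 0.0])

    def test_mixed_toy_hand_product_limit(self):
        # events at 2 and 4; censorings at 3, 5, 6
        out = SurvivalOutcome(np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
                              np.array([1, 0, 1, 0, 0]))
        km = km_estimate(out)["all"]
        # S(2) = 4/5; S(4) = 4/5 * 2/3 = 8/15
        s = dict(zip(km.times, km.survival))
        assert np.isclose(s[2.0], 4 / 5)
        assert np.isclose(s[4.0], 8 / 15)

    def test_grouped_estimation(self):
        out = SurvivalOutcome(np.arange(1.0, 9.0), np.ones(8, dtype=int))
        curves = km_estimate(out, groups=np.repeat(["a", "b"], 4))
        assert set(curves) == {"a", "b"}
        assert curves["a"].n == 4


def brute_force_logrank(time, event, groups):
    """O-E chi-square statistic summed over event times, from scratch."""
    g1 = np.asarray(groups) == np.unique(groups)[1]
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        out = SurvivalOutcome(np.r_[t, t], np.r_[e, e])
        stat, df, p = logrank_test(out, np.repeat([0, 1], 5))
        assert stat < 1e-10 and df == 1 and p > 0.999

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(21)
        t = np.r_[rng.uniform(0, 5, 12), rng.uniform(4, 12, 12)]
        e = rng.integers(0, 2, 24)
        e[[0, -1]] = 1
        g = np.repeat([0, 1], 12)
        out = SurvivalOutcome(t, e)
        stat, _, _ = logrank_test(out, g)
        assert np.isclose(stat, brute_force_logrank(t, e, g), rtol=1e-10)

    def test_permutation_null_mean_near_df(self):
        rng = np.random.default_rng(22)
        out = random_survival(rng, 60)
        stats = []
        for _ in range(200):
            g = rng.permutation(np.repeat([0, 1], 30))
            s, _, _ = logrank_test(out, g)
            stats.append(s)
        assert abs(np.mean(stats) - 1.0) < 0.25  # chi2(1) mean


class TestReverseKM:
    def test_all_events_not_reached(self):
        out = SurvivalOutcome(np.arange(1.0, 7.0), np.ones(6, dtype=int))
        assert np.isnan(reverse_km_median_followup(out))

    def test_no_events_equals_plain_median(self):
        t = np.array([3.0, 9.0, 12.0, 20.0, 26.0])
        out = SurvivalOutcome(t, np.zeros(5, dtype=int))
        assert reverse_km_median_followup(out) == np.median(t)

    def test_symmetric_toy_hand_value(self):
        # censorings (reverse events) at 10 and 30, events at 5 and 50:
        # reverse-KM drops below 0.5 at t=30
        out = SurvivalOutcome(np.array([5.0, 10.0, 30.0, 50.0]),
                              np.array([1, 0, 0, 1]))
        assert reverse_km_median_followup(out) == 30.0


def grid_search_cox_beta(x, outcome, lo=-5, hi=5, step=1e-4):
    """Brute-force maximizer of the Breslow partial likelihood."""
    betas = np.arange(lo, hi + step, step)
    lls = [breslow_loglik(b * x, outcome) for b in betas]
    return betas[int(np.argmax(lls))]


class TestCox:
    def test_exchangeable_outcome_gives_null_beta(self, toy_outcome):
        out, _ = toy_outcome
        x = np.tile([1.0, 0.0], 5)
        # exactly symmetric dataset: every record appears with both labels,
        # so the likelihood is invariant under beta -> -beta
        out2 = SurvivalOutcome(np.r_[out.time, out.time],
                               np.r_[out.event, out.event])
        x2 = np.r_[x, 1 - x]
        fit = fit_cox(x2[:, None], out2)
        assert abs(fit.beta.iloc[0]) < 1e-6

    def test_matches_grid_search_oracle(self, toy_outcome):
        out, x = toy_outcome
        fit = fit_cox(x[:, None], out)
        oracle = grid_search_cox_beta(x, out)
        assert abs(fit.beta.iloc[0] - oracle) < 1e-3

    def test_duplicating_dataset_leaves_beta_unchanged(self, toy_outcome):
        out, x = toy_outcome
        fit1 = fit_cox(x[:, None], out)
        out2 = SurvivalOutcome(np.r_[out.time, out.time],
                               np.r_[out.event, out.event])
        fit2 = fit_cox(np.r_[x, x][:, None], out2)
        assert np.allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-6)

    def test_wald_interval_brackets_hr(self, toy_outcome):
        out, x = toy_outcome
        fit = fit_cox(x[:, None], out)
        ci = fit.conf_int
        assert (ci["hr_lower95"].iloc[0] < fit.hr.iloc[0] < ci["hr_upper95"].iloc[0])
        assert fit.hr.iloc[0] > 0

    def test_separation_raises(self):
        # covariate perfectly orders events before censorings
        t = np.r_[np.arange(1.0, 6.0), np.arange(10.0, 15.0)]
        e = np.r_[np.ones(5, int), np.zeros(5, int)]
        x = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ConvergenceError):
            fit_cox(x[:, None], SurvivalOutcome(t, e))

    def test_constant_column_rejected(self, toy_outcome):
        out, _ = toy_outcome
        with pytest.raises(ValueError, match="constant"):
            fit_cox(np.ones((10, 1)), out)


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(30)
    n, p = 100, 5
    X = rng.standard_normal((n, p))
    beta = np.array([0.9, -0.7, 0.0, 0.0, 0.0])
    T = 25 * np.exp(-X @ beta) * rng.exponential(1, n) ** (1 / 1.2)
    C = rng.uniform(10, 60, n)
    out = SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))
    return X, out


class TestPenalizedCox:
    def test_all_zero_at_lambda_max(self, design):
        X, out = design
        lmax = compute_lambda_max(X, out, alpha=0.9)
        for lam in (lmax, lmax * 1.7):
            fit = fit_penalized_cox(X, out, lam=lam, alpha=0.9)
            assert np.all(fit.beta.to_numpy() == 0.0)
        just_below = fit_penalized_cox(X, out, lam=lmax * 0.98, alpha=0.9)
        assert just_below.n_nonzero >= 1

    def test_small_lambda_matches_unpenalized(self, design):
        X, out = design
        X2 = X[:50, :2]
        out2 = out.subset(np.arange(50))
        pen = fit_penalized_cox(X2, out2, lam=1e-7, alpha=0.9, tol=1e-9)
        ref = fit_cox(X2, out2)
        assert np.max(np.abs(pen.beta.to_numpy() - ref.beta.to_numpy())) < 1e-3

    def test_local_optimality_probe(self, design):
        """Objective at the fit beats 10,000 random perturbations."""
        X, out = design
        lam, alpha = 0.08, 0.9
        fit = fit_penalized_cox(X, out, lam=lam, alpha=alpha, tol=1e-10)
        Xstd = (X - fit.center) / fit.scale
        beta_std = fit.beta.to_numpy() * fit.scale
        n = len(out)

        def objective(b):
            pen = lam * (alpha * np.abs(b).sum() + (1 - alpha) / 2 * (b ** 2).sum())
            return -breslow_loglik(Xstd @ b, out) / n + pen

        f0 = objective(beta_std)
        rng = np.random.default_rng(31)
        perturbed = beta_std + rng.uniform(-1e-3, 1e-3, size=(10000, len(beta_std)))
        vals = np.array([objective(b) for b in perturbed])
        assert np.all(vals >= f0 - 1e-12)

    def test_l1_norm_never_exceeds_unpenalized(self, design):
        X, out = design
        X2 = X[:, :3]
        ref_l1 = np.abs(fit_cox(X2, out).beta.to_numpy()).sum()
        for lam in (0.01, 0.05, 0.2):
            fit = fit_penalized_cox(X2, out, lam=lam, alpha=0.9)
            assert np.abs(fit.beta.to_numpy()).sum() <= ref_l1 + 1e-8

    def test_matches_coxnet_reference(self, design):
        """Independent implementation cross-check (scikit-survival)."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        X, out = design
        Xstd = (X - X.mean(0)) / X.std(0)
        lam = 0.05
        ref = CoxnetSurvivalAnalysis(l1_ratio=0.9, alphas=[lam], tol=1e-10,
                                     normalize=False)
        ref.fit(Xstd, Surv.from_arrays(out.event.astype(bool), out.time))
        fit = fit_penalized_cox(Xstd, out, lam=lam, alpha=0.9, tol=1e-10)
        assert np.max(np.abs(fit.beta.to_numpy() - ref.coef_[:, 0])) < 1e-4

    def test_unpenalized_block_free_at_lambda_max(self, design):
        X, out = design
        pf = np.array([1.0, 1, 1, 0, 0])
        lmax = compute_lambda_max(X, out, alpha=0.9, penalty_factor=pf)
        fit = fit_penalized_cox(X, out, lam=lmax * 2, alpha=0.9, penalty_factor=pf)
        b = fit.beta.to_numpy()
        assert np.all(b[:3] == 0.0) and np.any(b[3:] != 0.0)

    def test_path_is_deterministic(self, design):
        X, out = design
        f1 = penalized_cox_path(X, out)
        f2 = penalized_cox_path(X, out)
        assert np.array_equal(f1.beta_path, f2.beta_path)


class TestLambdaSelection:
    def test_pure_noise_selects_sparse_model(self):
        rng = np.random.default_rng(33)
        X = rng.standard_normal((90, 40))
        out = random_survival(rng, 90)
        sel = select_lambda_cv(X, out, k=5, seed=1)
        fit = fit_penalized_cox(X, out, lam=sel.lambda_opt)
        assert fit.n_nonzero <= 10

    def test_strong_predictor_selected(self):
        rng = np.random.default_rng(34)
        n = 120
        X = rng.standard_normal((n, 10))
        T = 25 * np.exp(-1.2 * X[:, 0]) * rng.exponential(1, n)
        C = rng.uniform(10, 60, n)
        out = SurvivalOutcome(np.minimum(T, C), (T <= C).astype(int))
        sel = select_lambda_cv(X, out, k=5, seed=2)
        fit = fit_penalized_cox(X, out, lam=sel.lambda_opt)
        assert fit.beta.iloc[0] > 0.5  # higher x0 -> higher hazard, retained

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(35)
        X = rng.standard_normal((70, 15))
        out = random_survival(rng, 70)
        s1 = select_lambda_cv(X, out, k=5, seed=9)
        s2 = select_lambda_cv(X, out, k=5, seed=9)
        assert s1.lambda_opt == s2.lambda_opt
        assert np.array_equal(s1.cv_deviance, s2.cv_deviance)


class TestPrognosticIndex:
    def test_zero_beta_gives_zero_scores(self):
        rng = np.random.default_rng(36)
        X = rng.standard_normal((30, 4))
        out = random_survival(rng, 30)
        lmax = compute_lambda_max(X, out)
        fit = fit_penalized_cox(X, out, lam=lmax * 2)
        assert np.allclose(prognostic_index(fit, X), 0.0)

    def test_hand_dot_product(self, toy_outcome):
        out, x = toy_outcome
        z = np.array([0.3, -0.2, 0.5, 0.1, -0.4, 0.2, -0.1, 0.4, -0.3, 0.0])
        X = np.column_stack([x, z])
        fit = fit_cox(X, out)
        scores = prognostic_index(fit, X[:3])
        assert np.allclose(scores, X[:3] @ fit.beta.to_numpy())

    def test_single_column_proportionality(self, toy_outcome):
        out, x = toy_outcome
        fit = fit_cox(x[:, None], out)
        s = prognostic_index(fit, x[:, None])
        assert np.allclose(s, fit.beta.iloc[0] * x)
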