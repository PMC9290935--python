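"""Estimator suite: centring, model equivalences, the exact marginal
likelihood against brute-force integration, and the errors-in-variables
extension."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats
from scipy.special import logsumexp

import crosslag as cl
from crosslag import _kalman
from crosslag.estimators import (_lagged_frame, dyn_sem_marginal_loglik,
                                 fit_dyn_ldvm, fit_dyn_sem, fit_dyn_sem_plus,
                                 fit_stat_overall, fit_stat_within,
                                 within_subject_centre)
from crosslag.procsim import MeasurementErrorSpec, Panel, add_measurement_error


# ---------------------------------------------------------------------------
# within-subject centring
# ---------------------------------------------------------------------------

class TestCentring:
    def test_two_subject_example(self, tiny_panel):
        out = within_subject_centre(tiny_panel, "X")
        assert np.allclose(out.data["X_wc"], [-1, 1, -2, 2])

    def test_per_subject_means_are_zero(self, tradeoff_panel):
        out = within_subject_centre(tradeoff_panel, "X")
        means = out.data.groupby("subject")["X_wc"].mean()
        assert np.allclose(means, 0.0, atol=1e-12)

    def test_idempotent(self, tiny_panel):
        once = within_subject_centre(tiny_panel, "X")
        twice = within_subject_centre(once, "X_wc")
        assert np.allclose(twice.data["X_wc_wc"], once.data["X_wc"])

    def test_unknown_variable(self, tiny_panel):
        with pytest.raises(KeyError):
            within_subject_centre(tiny_panel, "W")


# ---------------------------------------------------------------------------
# static models
# ---------------------------------------------------------------------------

class TestStaticModels:
    def test_noiseless_single_subject_slope_exact(self):
        df = pd.DataFrame({"subject": 1, "time": range(1, 6),
                           "X": np.arange(5.0), "Y": 2.0 * np.arange(5.0)})
        res = fit_stat_overall(Panel(df))
        assert res.b_hat == pytest.approx(2.0, abs=1e-10)

    def test_four_point_ols(self):
        df = pd.DataFrame({"subject": 1, "time": [1, 2, 3, 4],
                           "X": [0.0, 1, 2, 3], "Y": [1.0, 3, 4, 7]})
        res = fit_stat_overall(Panel(df))
        assert res.b_hat == pytest.approx(1.9)
        assert res.estimates["a"] == pytest.approx(0.90)

    def test_single_subject_within_equals_overall(self, single_series_panel):
        a = fit_stat_overall(single_series_panel)
        b = fit_stat_within(single_series_panel)
        assert b.b_hat == pytest.approx(a.b_hat, abs=1e-9)

    def test_within_matches_mean_of_per_subject_slopes(self, tradeoff_panel):
        res = fit_stat_within(tradeoff_panel)
        slopes = []
        for _, d in tradeoff_panel.data.groupby("subject"):
            slopes.append(np.polyfit(d["X"], d["Y"], 1)[0])
        assert res.b_hat == pytest.approx(np.mean(slopes), abs=0.05)

    def test_constant_x_raises_or_warns(self):
        df = pd.DataFrame({"subject": 1, "time": [1, 2, 3],
                           "X": [1.0, 1.0, 1.0], "Y": [0.0, 1.0, 2.0]})
        with pytest.raises(np.linalg.LinAlgError):
            fit_stat_overall(Panel(df))

    def test_among_subject_confounding_hits_overall_not_within(self):
        # b=0, d=0, strong positive Omega: the cross-sectional model sees a
        # spurious positive slope, the within-subject model does not
        spec = cl.default_spec(
            "tradeoff_multi", b=0.0, d=0.0, n_subjects=150, n_time=6,
            omega=np.array([[1.0, 0.8], [0.8, 1.0]]))
        bo, bw = [], []
        for r in range(40):
            p = cl.simulate(spec.replace(seed=700 + r))
            bo.append(fit_stat_overall(p).b_hat)
            bw.append(fit_stat_within(p).b_hat)
        assert np.mean(bo) > 0.1
        assert abs(np.mean(bw)) < 3 * np.std(bw) / np.sqrt(len(bw)) + 0.01


# ---------------------------------------------------------------------------
# lagged-dependent-variable model
# ---------------------------------------------------------------------------

class TestDynLdvm:
    def test_superfluous_lag_on_exogenous_data(self):
        spec = cl.default_spec("tradeoff_multi", b=0.5, d=0.0,
                               omega=np.zeros((2, 2)), n_subjects=200,
                               n_time=12)
        res = fit_dyn_ldvm(cl.simulate(spec.replace(seed=11)))
        assert res.b_hat == pytest.approx(0.5, abs=0.05)
        assert abs(res.estimates["gamma"]) < 0.1

    def test_first_rows_dropped(self, tradeoff_panel):
        res = fit_dyn_ldvm(tradeoff_panel)
        S, T = 60, 10
        assert res.n_obs == S * (T - 1)

    def test_two_step_series_rejected(self):
        df = pd.DataFrame({"subject": [1, 1, 2, 2], "time": [1, 2, 1, 2],
                           "X": [0.0, 1, 2, 3], "Y": [1.0, 0, 2, 1]})
        with pytest.raises(ValueError, match="single observation"):
            fit_dyn_ldvm(Panel(df))

    def test_gap_rows_not_lagged_across(self):
        df = pd.DataFrame({"subject": 1, "time": [1, 2, 3, 7, 8, 9],
                           "X": np.arange(6.0),
                           "Y": [0.1, 0.5, 0.2, 0.9, 0.3, 0.7]})
        lagged = _lagged_frame(df, ["Y"]).dropna(subset=["Y_lag"])
        assert set(lagged["time"]) == {2, 3, 8, 9}


# ---------------------------------------------------------------------------
# DYN_SEM
# ---------------------------------------------------------------------------

def _mc_marginal_loglik(panel, structure, params, n_draws, seed,
                        initial_condition=False):
    """Brute-force Monte-Carlo integration over (mu, nu) per subject."""
    rng = np.random.default_rng(seed)
    omega = np.asarray(params["omega"], float)
    has_z = structure in ("grouplive", "density")
    total = 0.0
    for _, d in panel.data.groupby("subject"):
        d = d.sort_values("time")
        u = rng.multivariate_normal(np.zeros(2), omega, size=n_draws)
        mu, nu = u[:, 0], u[:, 1]
        ll = np.zeros(n_draws)
        X, Y = d["X"].to_numpy(), d["Y"].to_numpy()
        if initial_condition:
            mean0 = (params["x0_mean"] + params["lambda_mu"] * mu
                     + params["lambda_nu"] * nu)
            ll += stats.norm.logpdf(X[0], mean0, params["sigma_x0"])
        for t in range(len(d)):
            mean_y = params["a"] + params["b"] * X[t] + mu
            ll += stats.norm.logpdf(Y[t], mean_y, params["sigma_eps"])
        if has_z:
            Z = d["Z"].to_numpy()
            for t in range(len(d)):
                ll += stats.norm.logpdf(Z[t], params["g"] + nu,
                                        params["sigma_lambda"])
        for t in range(1, len(d)):
            mean_x = params["c"] + params["d"] * Y[t - 1]
            if has_z:
                mean_x = mean_x + params["f"] * Z[t - 1] * X[t - 1]
            else:
                mean_x = mean_x + nu
            ll += stats.norm.logpdf(X[t], mean_x, params["sigma_kappa"])
        total += logsumexp(ll) - np.log(n_draws)
    return total


class TestDynSem:
    @pytest.mark.parametrize("structure,kind", [
        ("tradeoff", "tradeoff_multi"), ("grouplive", "grouplive_multi")])
    def test_marginal_loglik_matches_mc_integration(self, structure, kind):
        """Analytic random-effect integration equals brute-force Monte-Carlo
        on a tiny instance (S=3, T=3)."""
        panel = cl.simulate(cl.default_spec(kind, n_subjects=3, n_time=3,
                                            seed=21))
        params = dict(a=0.1, b=0.4, c=-0.1, d=-0.3, f=0.2, g=0.5,
                      sigma_eps=1.1, sigma_kappa=0.9, sigma_lambda=0.4,
                      omega=np.array([[0.5, 0.2], [0.2, 0.4]]))
        ours = dyn_sem_marginal_loglik(panel, structure, params)
        mc = _mc_marginal_loglik(panel, structure, params, 6_000_000, seed=1)
        assert ours == pytest.approx(mc, abs=0.01)

    def test_marginal_loglik_with_initial_condition_rows(self):
        panel = cl.simulate(cl.default_spec("tradeoff_multi", n_subjects=3,
                                            n_time=3, seed=22))
        params = dict(a=0.0, b=0.5, c=0.0, d=-0.4, sigma_eps=1.0,
                      sigma_kappa=1.0, x0_mean=0.2, sigma_x0=1.2,
                      lambda_mu=-0.3, lambda_nu=0.8,
                      omega=np.array([[0.5, 0.2], [0.2, 0.4]]))
        ours = dyn_sem_marginal_loglik(panel, "tradeoff", params,
                                       initial_condition=True)
        mc = _mc_marginal_loglik(panel, "tradeoff", params, 6_000_000, seed=2,
                                 initial_condition=True)
        assert ours == pytest.approx(mc, abs=0.01)

    def test_single_series_equals_stat_overall_exactly(self, single_series_panel):
        sem = fit_dyn_sem(single_series_panel, "tradeoff")
        stat = fit_stat_overall(single_series_panel)
        assert sem.b_hat == pytest.approx(stat.b_hat, abs=1e-10)

    def test_z_required_for_z_structures(self, tradeoff_panel):
        with pytest.raises(ValueError, match="Z"):
            fit_dyn_sem(tradeoff_panel, "grouplive")

    def test_recovers_b_on_tradeoff(self):
        spec = cl.default_spec("tradeoff_multi", n_subjects=100, n_time=10)
        vals = [fit_dyn_sem(cl.simulate(spec.replace(seed=900 + r)),
                            "tradeoff").b_hat for r in range(60)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(0.5, abs=3 * se + 0.005)

    def test_dropping_crosslag_or_intercept_correlation_reinstates_bias(self):
        """Both the cross-lag path and the intercept correlation are needed;
        removing either pushes the estimate back toward the static one."""
        spec = cl.default_spec("tradeoff_multi", n_subjects=100, n_time=10)
        full, no_cl, no_corr = [], [], []
        for r in range(40):
            p = cl.simulate(spec.replace(seed=950 + r))
            full.append(fit_dyn_sem(p, "tradeoff").b_hat)
            no_cl.append(fit_dyn_sem(p, "tradeoff",
                                     include_crosslag=False).b_hat)
            no_corr.append(fit_dyn_sem(p, "tradeoff",
                                       correlated_intercepts=False).b_hat)
        assert abs(np.mean(full) - 0.5) < 0.01
        # negative cross-lag => upward bias when the model is crippled
        assert np.mean(no_cl) > 0.515
        assert np.mean(no_corr) > 0.515


# ---------------------------------------------------------------------------
# DYN_SEM+
# ---------------------------------------------------------------------------

def _tradeoff_joint_normal_loglik(theta, Xo, Yo, vx, vy):
    """Independent oracle for the trade-off errors-in-variables likelihood:
    the per-subject joint normal over observed vectors built by linear
    propagation of the stationary VAR(1), instead of sequential filtering."""
    a, b, c, d = theta[:4]
    se, sk = np.exp(theta[4:6])
    l11, l22, l21 = np.exp(theta[6]), np.exp(theta[7]), theta[8]
    Lc = np.array([[l11, 0], [l21, l22]])
    omega = Lc @ Lc.T
    S, T = Xo.shape
    A = np.array([[0.0, d], [0.0, b * d]])
    k0 = np.array([c, a + b * c])
    m = np.linalg.solve(np.eye(2) - A, k0)
    Q = np.array([[sk ** 2, b * sk ** 2],
                  [b * sk ** 2, b ** 2 * sk ** 2 + se ** 2]])
    P = linalg.solve_discrete_lyapunov(A, Q)
    B = np.array([[0.0, 1.0], [1.0, b]])
    M = np.linalg.solve(np.eye(2) - A, B)
    # Cov(s_{t+h}, s_t) = A^h P for the de-meaned stationary process
    Gam = np.zeros((2 * T, 2 * T))
    for t in range(T):
        for s in range(T):
            h = t - s
            blk = (np.linalg.matrix_power(A, h) @ P if h >= 0
                   else P @ np.linalg.matrix_power(A, -h).T)
            Gam[2 * t:2 * t + 2, 2 * s:2 * s + 2] = blk
    J = np.tile(M, (T, 1))
    Sigma = Gam + J @ omega @ J.T + np.diag(np.tile([vx, vy], T))
    mean = np.tile(m, T)
    obs = np.empty((S, 2 * T))
    obs[:, 0::2] = Xo
    obs[:, 1::2] = Yo
    return float(np.sum(stats.multivariate_normal.logpdf(obs, mean, Sigma)))


class TestDynSemPlus:
    def test_zero_error_variances_reduce_to_dyn_sem(self, tradeoff_panel):
        pe = add_measurement_error(tradeoff_panel, MeasurementErrorSpec(0, 0, seed=1))
        plus = fit_dyn_sem_plus(pe, "tradeoff", (0.0, 0.0))
        sem = fit_dyn_sem(tradeoff_panel, "tradeoff")
        assert plus.b_hat == pytest.approx(sem.b_hat, abs=1e-12)
        assert plus.model == "DYN_SEM_PLUS"

    def test_error_variance_exceeding_observed_variance_rejected(self, tradeoff_panel):
        pe = add_measurement_error(tradeoff_panel,
                                   MeasurementErrorSpec(0.25, 0.0, seed=1))
        big = 10.0 * pe.data["X_obs"].var()
        with pytest.raises(ValueError, match="exceeds"):
            fit_dyn_sem_plus(pe, "tradeoff", (big, 0.0))

    def test_missing_observed_columns_rejected(self, tradeoff_panel):
        with pytest.raises(ValueError, match="X_obs"):
            fit_dyn_sem_plus(tradeoff_panel, "tradeoff", (0.1, 0.0))

    def test_filter_matches_joint_normal_oracle(self):
        """Sequential Kalman evaluation equals the independently built
        per-subject joint-normal likelihood (trade-off structure)."""
        panel = cl.simulate(cl.default_spec("tradeoff_multi", n_subjects=4,
                                            n_time=5, seed=33))
        pe = add_measurement_error(panel, MeasurementErrorSpec(0.25, 0.25, seed=3))
        obs = pe.using_observed().data.sort_values(["subject", "time"])
        Xo = obs["X"].to_numpy().reshape(4, 5)
        Yo = obs["Y"].to_numpy().reshape(4, 5)
        vx, vy = pe.error_variances["X"], pe.error_variances["Y"]
        theta = np.array([0.1, 0.45, -0.1, -0.5, np.log(0.9), np.log(1.1),
                          np.log(0.7), np.log(0.6), 0.3])
        ours = -0.5 * _kalman.sem_plus_neg2ll(theta, Xo, Yo, None, "tradeoff",
                                              vx, vy, True)
        oracle = _tradeoff_joint_normal_loglik(theta, Xo, Yo, vx, vy)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_attenuation_corrected_on_tradeoff(self):
        """X-error attenuates the naive fit; the latent model recovers b."""
        spec = cl.default_spec("tradeoff_multi", n_subjects=100, n_time=10)
        naive, plus = [], []
        for r in range(25):
            p = cl.simulate(spec.replace(seed=1200 + r))
            pe = add_measurement_error(p, MeasurementErrorSpec(0.25, 0.0,
                                                               seed=1300 + r))
            naive.append(fit_dyn_sem(pe.using_observed(), "tradeoff").b_hat)
            plus.append(fit_dyn_sem_plus(
                pe, "tradeoff", (pe.error_variances["X"], 0.0),
                compute_se=False).b_hat)
        assert np.mean(naive) < 0.40            # attenuated toward zero
        se = np.std(plus) / np.sqrt(len(plus))
        assert np.mean(plus) == pytest.approx(0.5, abs=3 * se + 0.01)
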