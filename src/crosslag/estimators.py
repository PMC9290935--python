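"""Estimators of the contemporaneous effect ``b`` for cross-lagged panels.

Five models are provided, all returning a comparable :class:`FitResult`:

``STAT_OVERALL``
    Conventional cross-sectional static mixed model
    ``Y ~ 1 + X + (1 | subject)`` fitted by maximum likelihood (ordinary
    least squares for a single subject).  Confounds within- and
    among-subject associations.

``STAT_WITHIN``
    As above with X replaced by its within-subject-centred version, which
    filters out the masking effect of among-subject covariance but
    re-introduces the short-series cross-lag bias.

``DYN_LDVM``
    Lagged-dependent-variable model: adds the within-subject-centred
    ``Y[t-1]`` as a covariate to absorb the response autocorrelation that
    the cross-lag induces.

``DYN_SEM``
    The dynamical structural-equation model: jointly maximizes the exact
    marginal likelihood of the multi-equation system (Y-, X- and, where
    applicable, Z-equations) with correlated subject-level random
    intercepts integrated out analytically.  Conditional on each subject's
    first observation the system is a stacked linear mixed model with
    response-specific residual variances; for a single subject all random
    terms drop and the ``b`` estimate coincides exactly with STAT_OVERALL's.

``DYN_SEM_PLUS``
    Errors-in-variables extension: the true series are latent, observed
    with known measurement-error variances; the exact marginal likelihood
    is evaluated by a Kalman filter (see :mod:`crosslag._kalman`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _gls, _kalman
from .procsim import Panel

__all__ = [
    "FitResult",
    "standardized_effect",
    "within_subject_centre",
    "fit_stat_overall",
    "fit_stat_within",
    "fit_dyn_ldvm",
    "fit_dyn_sem",
    "fit_dyn_sem_plus",
    "dyn_sem_marginal_loglik",
    "STRUCTURES",
]

STRUCTURES = ("tradeoff", "grouplive", "density")
_Z_STRUCTURES = ("grouplive", "density")


@dataclass
class FitResult:
    """Point estimates and Wald inference for one fitted model."""

    model: str
    estimates: dict
    b_hat: float
    se_b: float
    ci_b: Tuple[float, float]
    p_value_b: float
    loglik: float
    converged: bool
    b_standardized: float
    n_obs: int = 0
    n_subjects: int = 0
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "b_hat": self.b_hat,
            "se_b": self.se_b,
            "ci_b_lower": self.ci_b[0],
            "ci_b_upper": self.ci_b[1],
            "p_value_b": self.p_value_b,
            "loglik": self.loglik,
            "converged": self.converged,
            "b_standardized": self.b_standardized,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }
        for k, v in self.estimates.items():
            d[f"est_{k}"] = v
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=float)


def _wald(b, se):
    if se <= 0 or not np.isfinite(se):
        return (np.nan, np.nan), np.nan
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return (b - half, b + half), p


def standardized_effect(panel: Panel, b: float, how: str = "sd") -> float:
    """Rescale b by the spread ratio of X to Y.

    ``how='sd'`` (the default used in FitResult) multiplies by
    ``sd(X)/sd(Y)``; ``how='var'`` uses the variance ratio instead — both
    conventions appear in the literature and neither is asserted as
    canonical here.
    """
    if how not in ("sd", "var"):
        raise ValueError("how must be 'sd' or 'var'")
    sx = panel.data["X"].std(ddof=1)
    sy = panel.data["Y"].std(ddof=1)
    if sy == 0:
        return np.nan
    r = sx / sy
    return b * (r ** 2 if how == "var" else r)


_standardize = standardized_effect


# ---------------------------------------------------------------------------
# centring and design helpers
# ---------------------------------------------------------------------------

def within_subject_centre(panel: Panel, variable: str) -> Panel:
    """Append ``<variable>_wc``: the value minus that subject's mean.

    Idempotent: centring an already-centred column returns the same values.
    """
    if variable not in panel.data.columns:
        raise KeyError(f"unknown variable {variable!r}")
    df = panel.data.copy()
    df[variable + "_wc"] = (
        df[variable] - df.groupby("subject")[variable].transform("mean")
    )
    return Panel(df, spec=panel.spec, intercepts=panel.intercepts,
                 error_variances=panel.error_variances)


def _check_constant_x(df, res: FitResult):
    sds = df.groupby("subject")["X"].std(ddof=0)
    n_const = int((sds == 0).sum())
    if n_const and df["subject"].nunique() > 1:
        msg = f"{n_const} subject(s) with constant X contribute only to intercept/variance terms"
        warnings.warn(msg)
        res.warnings.append(msg)


def _lmm_fit_result(model, panel, y, X, groups, b_index, names) -> FitResult:
    df = panel.data
    if df["subject"].nunique() == 1 or len(np.unique(groups)) == 1:
        fit = _gls.fit_random_intercept_lmm(y, X, np.zeros(len(y)))
    else:
        fit = _gls.fit_random_intercept_lmm(y, X, groups)
    b = float(fit.beta[b_index])
    se = float(np.sqrt(fit.cov_beta[b_index, b_index]))
    ci, p = _wald(b, se)
    est = {nm: float(v) for nm, v in zip(names, fit.beta)}
    est["sigma_resid"] = float(np.sqrt(fit.sigma2))
    est["sd_subject"] = float(np.sqrt(fit.tau2))
    res = FitResult(model=model, estimates=est, b_hat=b, se_b=se, ci_b=ci,
                    p_value_b=p, loglik=float(fit.loglik),
                    converged=bool(fit.converged),
                    b_standardized=_standardize(panel, b),
                    n_obs=fit.n_obs, n_subjects=df["subject"].nunique())
    _check_constant_x(df, res)
    return res


# ---------------------------------------------------------------------------
# static models and the lagged-dependent-variable model
# ---------------------------------------------------------------------------

def fit_stat_overall(panel: Panel) -> FitResult:
    """Cross-sectional static (mixed) regression of Y on X."""
    df = panel.data
    if len(df) < 2:
        raise ValueError("need at least 2 records")
    X = np.column_stack([np.ones(len(df)), df["X"].to_numpy(float)])
    return _lmm_fit_result("STAT_OVERALL", panel, df["Y"].to_numpy(float), X,
                           df["subject"].to_numpy(), 1, ["a", "b"])


def fit_stat_within(panel: Panel) -> FitResult:
    """Static regression on within-subject-centred X."""
    p2 = within_subject_centre(panel, "X")
    df = p2.data
    X = np.column_stack([np.ones(len(df)), df["X_wc"].to_numpy(float)])
    res = _lmm_fit_result("STAT_WITHIN", panel, df["Y"].to_numpy(float), X,
                          df["subject"].to_numpy(), 1, ["a", "b"])
    res.model = "STAT_WITHIN"
    return res


def _lagged_frame(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    d = df.sort_values(["subject", "time"]).copy()
    g = d.groupby("subject")
    for col in cols:
        d[col + "_lag"] = g[col].shift(1)
        contiguous = g["time"].diff() == 1
        d.loc[~contiguous.fillna(False), col + "_lag"] = np.nan
    return d


def fit_dyn_ldvm(panel: Panel) -> FitResult:
    """Mixed model with within-subject-centred lagged Y as extra covariate."""
    d = _lagged_frame(panel.data, ["Y"])
    d = d.dropna(subset=["Y_lag"])
    counts = d.groupby("subject").size()
    if (counts < 2).any() and len(counts) > 1:
        bad = counts[counts < 2].index.tolist()
        raise ValueError(
            f"subjects {bad} have a single observation after lagging; "
            "within-subject centring of the lagged response is degenerate"
        )
    d["Ylag_wc"] = d["Y_lag"] - d.groupby("subject")["Y_lag"].transform("mean")
    X = np.column_stack([np.ones(len(d)), d["X"].to_numpy(float),
                         d["Ylag_wc"].to_numpy(float)])
    sub = Panel(d[[c for c in ("subject", "time", "X", "Y", "Z") if c in d.columns]],
                spec=panel.spec)
    return _lmm_fit_result("DYN_LDVM", sub, d["Y"].to_numpy(float), X,
                           d["subject"].to_numpy(), 1, ["a", "b", "gamma"])


# ---------------------------------------------------------------------------
# DYN_SEM
# ---------------------------------------------------------------------------

def _sem_design(panel: Panel, structure: str, include_crosslag=True,
                initial_condition=False):
    """Per-subject stacked design grouped by row layout (series length).

    With ``initial_condition`` the first X observation of every subject is
    modelled too (free mean, free loadings on the random intercepts, free
    residual SD) rather than conditioned on; under stationarity X[1] is
    correlated with the intercepts, and ignoring that correlation biases
    the contemporaneous effect.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}")
    has_z = structure in _Z_STRUCTURES
    if has_z and not panel.has_z:
        raise ValueError(f"structure {structure!r} requires a Z column")
    d = _lagged_frame(panel.data, ["X", "Y"] + (["Z"] if has_z else []))

    # fixed-effect columns: [a, b] (Y rows), [c, d(, f)] (X rows)(, [g] Z rows)
    names = ["a", "b", "c"] + (["d"] if include_crosslag else []) \
        + (["f", "g"] if has_z else [])
    if initial_condition:
        names.append("x0_mean")
    p = len(names)
    col = {nm: i for i, nm in enumerate(names)}

    groups = {}
    for subj, ds in d.groupby("subject", sort=True):
        ds = ds.sort_values("time")
        T = len(ds)
        if T < 2:
            raise ValueError(f"subject {subj!r} has fewer than 2 time steps")
        rows_y, rows_x, rows_z = [], [], []
        Xv = ds["X"].to_numpy(float)
        Yv = ds["Y"].to_numpy(float)
        Ylag = ds["Y_lag"].to_numpy(float)
        if has_z:
            Zv = ds["Z"].to_numpy(float)
            Xlag = ds["X_lag"].to_numpy(float)
            Zlag = ds["Z_lag"].to_numpy(float)
        y_list, X_list, L_list, r_list, free_list = [], [], [], [], []
        if initial_condition:
            row = np.zeros(p)
            row[col["x0_mean"]] = 1.0
            y_list.append(Xv[0]); X_list.append(row)
            L_list.append([0.0, 0.0]); r_list.append(3 if has_z else 2)
            free_list.append(True)
        for t in range(T):
            row = np.zeros(p)
            row[col["a"]] = 1.0
            row[col["b"]] = Xv[t]
            y_list.append(Yv[t]); X_list.append(row)
            L_list.append([1.0, 0.0]); r_list.append(0)
            free_list.append(False)
        for t in range(T):
            if not np.isfinite(Ylag[t]):
                continue
            row = np.zeros(p)
            row[col["c"]] = 1.0
            if include_crosslag:
                row[col["d"]] = Ylag[t]
            if has_z:
                row[col["f"]] = Zlag[t] * Xlag[t]
            y_list.append(Xv[t]); X_list.append(row)
            L_list.append([0.0, 1.0] if structure == "tradeoff" else [0.0, 0.0])
            r_list.append(1)
            free_list.append(False)
        if has_z:
            for t in range(T):
                row = np.zeros(p)
                row[col["g"]] = 1.0
                y_list.append(Zv[t]); X_list.append(row)
                L_list.append([0.0, 1.0]); r_list.append(2)
                free_list.append(False)
        key = (T, tuple(r_list))
        groups.setdefault(key, []).append(
            (np.array(y_list), np.array(X_list), np.array(L_list),
             np.array(r_list, int), np.array(free_list, bool)))

    blocks = []
    for key, items in groups.items():
        ys = np.stack([it[0] for it in items])
        Xs = np.stack([it[1] for it in items])
        blocks.append(_gls.LayoutBlock(y=ys, X=Xs, L=items[0][2],
                                       rtype=items[0][3],
                                       free_rows=items[0][4]))
    n_rtypes = (3 if has_z else 2) + (1 if initial_condition else 0)
    return blocks, names, n_rtypes


def _sem_fit_result(panel, structure, fit, names, model_name) -> FitResult:
    bi = names.index("b")
    b = float(fit.beta[bi])
    se = float(np.sqrt(fit.cov_beta[bi, bi]))
    ci, p = _wald(b, se)
    est = {nm: float(v) for nm, v in zip(names, fit.beta)}
    has_z = structure in _Z_STRUCTURES
    sig_names = ["sigma_eps", "sigma_kappa"] + (["sigma_lambda"] if has_z else [])
    if len(fit.sigmas) > len(sig_names):
        sig_names.append("sigma_x0")
    for nm, s in zip(sig_names, fit.sigmas):
        est[nm] = float(s)
    if fit.lam is not None:
        est["lambda_mu"], est["lambda_nu"] = map(float, fit.lam)
    est["omega_mu"] = float(fit.omega[0, 0])
    est["omega_nu"] = float(fit.omega[1, 1])
    est["omega_mu_nu"] = float(fit.omega[0, 1])
    return FitResult(model=model_name, estimates=est, b_hat=b, se_b=se,
                     ci_b=ci, p_value_b=p, loglik=float(fit.loglik),
                     converged=bool(fit.converged),
                     b_standardized=_standardize(panel, b),
                     n_obs=fit.n_obs, n_subjects=panel.n_subjects)


def fit_dyn_sem(panel: Panel, structure: str, include_crosslag: bool = True,
                include_random_intercepts: bool = True,
                correlated_intercepts: bool = True) -> FitResult:
    """Exact marginal ML fit of the dynamical structural-equation model.

    Conditional on each subject's first observation, the Y-, X- and (for
    the group-living and density structures) Z-equations form a stacked
    linear mixed model; the correlated random intercepts ``(mu, nu)`` are
    integrated out analytically.  For a single subject all random terms are
    dropped and ``b_hat`` equals STAT_OVERALL's exactly.  The options allow
    deliberately misspecified fits for sensitivity studies: dropping the
    cross-lag path, dropping the random intercepts entirely, or keeping
    them but severing their correlation (``correlated_intercepts=False``),
    which removes the only parameter shared between the equations.
    """
    with_re = include_random_intercepts and panel.n_subjects >= 2
    initial_condition = with_re and correlated_intercepts
    blocks, names, n_rtypes = _sem_design(panel, structure, include_crosslag,
                                          initial_condition=initial_condition)
    fit = _gls.fit_stacked_lmm(blocks, n_rtypes, with_re,
                               diag_omega=not correlated_intercepts)
    return _sem_fit_result(panel, structure, fit, names, "DYN_SEM")


def dyn_sem_marginal_loglik(panel: Panel, structure: str, params: dict,
                            initial_condition: bool = False) -> float:
    """Marginal log-likelihood of the DYN_SEM at fixed parameter values.

    ``params`` maps coefficient names (a, b, c, d[, f, g]), residual SDs
    (sigma_eps, sigma_kappa[, sigma_lambda]) and the among-subject
    covariance ``omega`` (2x2) to values; with ``initial_condition`` also
    x0_mean, sigma_x0 and the loadings lambda_mu, lambda_nu.  Used for
    oracle cross-checks against brute-force integration over the random
    intercepts.
    """
    blocks, names, n_rtypes = _sem_design(panel, structure,
                                          initial_condition=initial_condition)
    beta = np.array([params[nm] for nm in names], float)
    has_z = structure in _Z_STRUCTURES
    sig_names = ["sigma_eps", "sigma_kappa"] + (["sigma_lambda"] if has_z else [])
    lam = None
    if initial_condition:
        sig_names.append("sigma_x0")
        lam = np.array([params["lambda_mu"], params["lambda_nu"]], float)
    sigmas = np.array([params[nm] for nm in sig_names], float)
    omega = np.asarray(params.get("omega", np.zeros((2, 2))), float)
    return _gls.stacked_loglik_at(blocks, beta, sigmas, omega, lam=lam)


# ---------------------------------------------------------------------------
# DYN_SEM+ (errors-in-variables)
# ---------------------------------------------------------------------------

def _panel_matrices(panel: Panel, cols):
    d = panel.data.sort_values(["subject", "time"])
    counts = d.groupby("subject").size()
    if counts.nunique() != 1:
        raise ValueError("the errors-in-variables model requires balanced panels")
    S, T = len(counts), int(counts.iloc[0])
    return [d[c].to_numpy(float).reshape(S, T) for c in cols], S, T


def fit_dyn_sem_plus(panel: Panel, structure: str,
                     known_error_variances: Tuple[float, float],
                     compute_se: bool = True) -> FitResult:
    """Errors-in-variables dynamical SEM with known error variances.

    The true series are latent; their exact marginal likelihood (random
    intercepts and latent states integrated out) is evaluated by a batched
    Kalman filter and maximized by quasi-Newton.  With both error variances
    zero the measurement layer is the identity and the fit delegates to
    :func:`fit_dyn_sem`.
    """
    vx, vy = map(float, known_error_variances)
    if vx < 0 or vy < 0:
        raise ValueError("error variances must be non-negative")
    if not panel.has_observed:
        raise ValueError("panel provides no X_obs/Y_obs columns")
    obs = panel.using_observed()
    if vx == 0.0 and vy == 0.0:
        res = fit_dyn_sem(obs, structure)
        res.model = "DYN_SEM_PLUS"
        return res
    var_x = float(obs.data["X"].var(ddof=1))
    var_y = float(obs.data["Y"].var(ddof=1))
    if vx >= var_x or vy >= var_y:
        raise ValueError("known error variance exceeds the observed variance")

    has_z = structure in _Z_STRUCTURES
    cols = ["X", "Y"] + (["Z"] if has_z else [])
    (mats), S, T = _panel_matrices(obs, cols)
    Xo, Yo = mats[0], mats[1]
    Z = mats[2] if has_z else None
    with_re = S >= 2

    # warm starts: (i) the naive DYN_SEM fit on the observed values and
    # (ii) a deattenuation-corrected version of it (the naive optimum can
    # be a poor basin when the predictor carries substantial error)
    naive = fit_dyn_sem(obs, structure)
    est = naive.estimates
    rx = max(1.0 - vx / var_x, 0.2)
    ry = max(1.0 - vy / var_y, 0.2)

    def build(ests, corrected):
        e = dict(ests)
        if corrected:
            e["b"] = e["b"] / rx
            e["d"] = e["d"] / ry
            if has_z:
                e["f"] = e["f"] / rx
            e["sigma_eps"] = np.sqrt(max(
                e["sigma_eps"] ** 2 - e["b"] ** 2 * vx - vy,
                0.1 * e["sigma_eps"] ** 2))
            e["sigma_kappa"] = np.sqrt(max(
                e["sigma_kappa"] ** 2 - vx - e["d"] ** 2 * vy,
                0.1 * e["sigma_kappa"] ** 2))
        th = [e["a"], e["b"], e["c"], e["d"]]
        if has_z:
            th += [e["f"], e["g"]]
        th += [np.log(max(e["sigma_eps"], 1e-2)),
               np.log(max(e["sigma_kappa"], 1e-2))]
        if has_z:
            th.append(np.log(max(e["sigma_lambda"], 1e-2)))
        if with_re:
            w1 = np.sqrt(max(e["omega_mu"], 1e-4))
            w2 = np.sqrt(max(e["omega_nu"], 1e-4))
            l21 = e["omega_mu_nu"] / max(w1, 1e-6)
            l22 = np.sqrt(max(w2 ** 2 - l21 ** 2, 1e-4))
            th += [np.log(w1), np.log(l22), l21]
        if has_z:
            # free initial-condition model for the first latent X
            s0 = np.sqrt(max(np.var(Xo[:, 0], ddof=1) - vx,
                             0.05 * np.var(Xo[:, 0], ddof=1)))
            th += [float(np.mean(Xo[:, 0])), np.log(max(s0, 1e-2))]
            if with_re:
                th += [e.get("lambda_mu", 0.0), e.get("lambda_nu", 0.0)]
        return np.array(th, float)

    def obj(th):
        return _kalman.sem_plus_neg2ll(th, Xo, Yo, Z, structure, vx, vy, with_re)

    th_corr, th_naive = build(est, True), build(est, False)
    res = optimize.minimize(obj, th_corr, method="L-BFGS-B",
                            options={"maxiter": 2500, "ftol": 1e-12})
    # second basin check: restart from the uncorrected values only when the
    # first run failed or ended above the naive starting point
    if (not res.success) or res.fun > obj(th_naive):
        r2 = optimize.minimize(obj, th_naive, method="L-BFGS-B",
                               options={"maxiter": 2500, "ftol": 1e-12})
        if r2.fun < res.fun:
            res = r2
    converged = bool(res.success) and np.isfinite(res.fun)
    th = res.x

    names = ["a", "b", "c", "d"] + (["f", "g"] if has_z else [])
    (a, b, c, dd, f, g, se_, sk, sl, omega,
     m0x, s0, lx) = _kalman._unpack(th, structure, with_re)
    estd = dict(zip(names, [a, b, c, dd, f, g][:len(names)]))
    estd.update(sigma_eps=se_, sigma_kappa=sk)
    if has_z:
        estd["sigma_lambda"] = sl
        estd.update(x0_mean=float(m0x), sigma_x0=float(s0),
                    lambda_mu=float(lx[0]), lambda_nu=float(lx[1]))
    estd.update(omega_mu=float(omega[0, 0]), omega_nu=float(omega[1, 1]),
                omega_mu_nu=float(omega[0, 1]))

    bi = 1
    se_b = np.nan
    if compute_se:
        se_b = _hessian_se(obj, th, bi)
    ci, p = _wald(b, se_b) if np.isfinite(se_b) else ((np.nan, np.nan), np.nan)
    return FitResult(model="DYN_SEM_PLUS", estimates=estd, b_hat=float(b),
                     se_b=float(se_b), ci_b=ci, p_value_b=p,
                     loglik=-0.5 * float(res.fun), converged=converged,
                     b_standardized=_standardize(obs, float(b)),
                     n_obs=S * T * (3 if has_z else 2), n_subjects=S)


def _hessian_se(neg2ll, theta, index, rel_step=1e-4):
    """Wald SE of one parameter from a central-difference Hessian of the
    -2 log-likelihood (covariance = 2 * H^-1)."""
    k = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((k, k))
    f0 = neg2ll(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (neg2ll(theta + ei) - 2 * f0 + neg2ll(theta - ei)) / h[i] ** 2
            else:
                val = (neg2ll(theta + ei + ej) - neg2ll(theta + ei - ej)
                       - neg2ll(theta - ei + ej) + neg2ll(theta - ei - ej)) \
                      / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    try:
        cov = 2.0 * np.linalg.inv(H)
        v = cov[index, index]
        return float(np.sqrt(v)) if v > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan
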