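"""Maximum-likelihood solvers for the linear mixed models used by the
estimator suite.

Two solvers live here:

* :func:`fit_random_intercept_lmm` -- a fast profiled ML fit of
  ``y = X beta + u_group + e`` with a single Gaussian random intercept.
  The likelihood is profiled down to a one-dimensional search over the
  variance ratio ``rho = tau^2 / sigma^2`` (Woodbury identities give the
  GLS solution and log-determinant in closed form per group), which makes
  it cheap enough for Monte-Carlo studies with thousands of refits.

* :func:`fit_stacked_lmm` -- exact marginal ML for a stacked multi-response
  system with a bivariate random effect: per subject the response vector
  follows ``y_s = X_s beta + L u_s + e_s`` with ``u_s ~ MVN(0, Omega)``
  and heteroscedastic residuals (one SD per response type), i.e. marginal
  covariance ``V_s = L Omega L' + R``.  Fixed effects are profiled out by
  GLS at each variance-parameter value; Omega is parameterized via its
  Cholesky factor so the estimate is positive semidefinite by construction.
  Subjects sharing a row layout (equal series length) share one ``V`` and
  one Cholesky factorization per likelihood evaluation, so balanced panels
  cost a single small factorization per evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# random-intercept LMM (one grouping factor)
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int


def _ri_profile(rho: float, stats) -> tuple:
    """Profiled -2 log-likelihood pieces at variance ratio rho."""
    XtX, Xty, yty, Gx, Gy, ns, N = stats
    cs = rho / (1.0 + ns * rho)                      # (S,)
    A = XtX - np.einsum("s,si,sj->ij", cs, Gx, Gx)
    bvec = Xty - (cs * Gy) @ Gx
    beta = np.linalg.solve(A, bvec)
    rss = (yty - 2.0 * beta @ Xty + beta @ XtX @ beta
           - np.sum(cs * (Gy - Gx @ beta) ** 2))
    rss = max(rss, 1e-300)
    sigma2 = rss / N
    n2ll = N * (_LOG2PI + np.log(sigma2)) + np.sum(np.log1p(ns * rho)) + N
    return n2ll, beta, sigma2, A


def fit_random_intercept_lmm(y, X, groups) -> LmmFit:
    """ML fit of a Gaussian random-intercept mixed model.

    Parameters
    ----------
    y : (N,) response
    X : (N, p) fixed-effect design (include the intercept column)
    groups : (N,) group labels
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    groups = np.asarray(groups)
    N, p = X.shape
    uniq, idx = np.unique(groups, return_inverse=True)
    S = len(uniq)
    ns = np.bincount(idx).astype(float)
    Gx = np.zeros((S, p))
    for j in range(p):
        Gx[:, j] = np.bincount(idx, weights=X[:, j])
    Gy = np.bincount(idx, weights=y)
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < p:
        raise np.linalg.LinAlgError("singular fixed-effect design (non-estimable)")
    stats = (XtX, X.T @ y, float(y @ y), Gx, Gy, ns, N)

    def obj(t):
        return _ri_profile(np.exp(t), stats)[0]

    converged = True
    if S == 1:
        rho_hat = 0.0
    else:
        res = optimize.minimize_scalar(obj, bounds=(-14.0, 12.0), method="bounded",
                                       options={"xatol": 1e-10})
        converged = bool(res.success)
        rho_hat = float(np.exp(res.x))
        # compare against the boundary tau^2 = 0 (plain OLS)
        if _ri_profile(0.0, stats)[0] <= res.fun:
            rho_hat = 0.0
    n2ll, beta, sigma2, A = _ri_profile(rho_hat, stats)
    cov_beta = sigma2 * np.linalg.inv(A)
    return LmmFit(beta=beta, cov_beta=cov_beta, sigma2=sigma2,
                  tau2=rho_hat * sigma2, loglik=-0.5 * n2ll,
                  converged=converged, n_obs=N, n_groups=S)


# ---------------------------------------------------------------------------
# stacked multi-response LMM with bivariate random effect
# ---------------------------------------------------------------------------

@dataclass
class LayoutBlock:
    """Subjects sharing one row layout (same series length / row order)."""

    y: np.ndarray        # (Sg, n) responses
    X: np.ndarray        # (Sg, n, p) fixed-effect designs
    L: np.ndarray        # (n, 2) random-effect loadings
    rtype: np.ndarray    # (n,) int index into the residual-SD vector
    free_rows: np.ndarray = None  # (n,) bool; rows whose loadings are the
                                  # free (lam_mu, lam_nu) pair

    def __post_init__(self):
        if self.free_rows is None:
            self.free_rows = np.zeros(self.L.shape[0], bool)


@dataclass
class StackedFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigmas: np.ndarray
    omega: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    n_subjects: int
    lam: Optional[np.ndarray] = None  # initial-condition loadings on (mu, nu)


def _omega_from_phi(phi, k):
    l11, l22, l21 = np.exp(phi[k]), np.exp(phi[k + 1]), phi[k + 2]
    Lc = np.array([[l11, 0.0], [l21, l22]])
    return Lc @ Lc.T


def _stacked_neg2ll(phi, blocks: List[LayoutBlock], n_rtypes: int, with_re: bool):
    sigmas = np.exp(phi[:n_rtypes])
    omega = _omega_from_phi(phi, n_rtypes) if with_re else np.zeros((2, 2))
    has_free = any(blk.free_rows.any() for blk in blocks)
    lam = phi[n_rtypes + 3:n_rtypes + 5] if (with_re and has_free) else None
    p = blocks[0].X.shape[2]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    pieces = []
    const = 0.0
    for blk in blocks:
        Sg, n, _ = blk.X.shape
        V = np.diag(sigmas[blk.rtype] ** 2)
        if with_re:
            L = blk.L
            if lam is not None and blk.free_rows.any():
                L = L.copy()
                L[blk.free_rows] = lam
            V = V + L @ omega @ L.T
        try:
            cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf, None, None, sigmas, omega
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Xw = linalg.cho_solve(cho, blk.X.transpose(1, 0, 2).reshape(n, Sg * p))
        Xw = Xw.reshape(n, Sg, p).transpose(1, 0, 2)          # V^-1 X_s
        A += np.einsum("sni,snj->ij", blk.X, Xw)
        bvec += np.einsum("sni,sn->i", Xw, blk.y)
        const += Sg * (n * _LOG2PI + logdet)
        pieces.append((blk, cho))
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf, None, None, sigmas, omega
    quad = 0.0
    for blk, cho in pieces:
        resid = blk.y - np.einsum("snp,p->sn", blk.X, beta)
        rw = linalg.cho_solve(cho, resid.T)
        quad += float(np.sum(resid.T * rw))
    return const + quad, beta, A, sigmas, omega


def _stacked_neg2ll_grad(phi, blocks: List[LayoutBlock], n_rtypes: int):
    """Value and analytic gradient of the profiled -2 log-likelihood.

    With the fixed effects profiled out by GLS, the envelope theorem gives
    d(-2ll)/dphi_j = sum_blocks tr((Sg V^-1 - C) dV/dphi_j) where
    C = sum_s q_s q_s' and q_s = V^-1 r_s.
    """
    k = n_rtypes
    sigmas = np.exp(phi[:k])
    l11, l22, l21 = np.exp(phi[k]), np.exp(phi[k + 1]), phi[k + 2]
    Lc = np.array([[l11, 0.0], [l21, l22]])
    omega = Lc @ Lc.T
    has_free = any(blk.free_rows.any() for blk in blocks)
    lam = phi[k + 3:k + 5] if has_free else None
    n_par = len(phi)
    if np.max(np.abs(phi)) > 40:
        return np.inf, np.zeros(n_par)
    p = blocks[0].X.shape[2]

    A = np.zeros((p, p))
    bvec = np.zeros(p)
    pieces = []
    const = 0.0
    for blk in blocks:
        Sg, n, _ = blk.X.shape
        L = blk.L
        if lam is not None and blk.free_rows.any():
            L = L.copy()
            L[blk.free_rows] = lam
        V = np.diag(sigmas[blk.rtype] ** 2) + L @ omega @ L.T
        try:
            cho = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros(n_par)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Xw = linalg.cho_solve(cho, blk.X.transpose(1, 0, 2).reshape(n, Sg * p))
        Xw = Xw.reshape(n, Sg, p).transpose(1, 0, 2)
        A += np.einsum("sni,snj->ij", blk.X, Xw)
        bvec += np.einsum("sni,sn->i", Xw, blk.y)
        const += Sg * (n * _LOG2PI + logdet)
        pieces.append((blk, cho, L))
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(n_par)

    n2ll = const
    grad = np.zeros(n_par)
    # derivative pieces of Omega w.r.t. (log l11, log l22, l21)
    dLc = [np.array([[l11, 0.0], [0.0, 0.0]]),
           np.array([[0.0, 0.0], [0.0, l22]]),
           np.array([[0.0, 0.0], [1.0, 0.0]])]
    dOm = [dl @ Lc.T + Lc @ dl.T for dl in dLc]
    for blk, cho, L in pieces:
        Sg, n, _ = blk.X.shape
        resid = blk.y - np.einsum("snp,p->sn", blk.X, beta)
        q = linalg.cho_solve(cho, resid.T)              # (n, Sg)
        n2ll += float(np.sum(resid.T * q))
        Vinv = linalg.cho_solve(cho, np.eye(n))
        G = Sg * Vinv - q @ q.T                          # symmetric (n, n)
        dg = np.diag(G)
        for j in range(k):
            m = blk.rtype == j
            grad[j] += 2.0 * sigmas[j] ** 2 * float(np.sum(dg[m]))
        GL = G @ L                                       # (n, 2)
        Gt2 = L.T @ GL                                   # (2, 2)
        for jj in range(3):
            grad[k + jj] += float(np.sum(Gt2 * dOm[jj]))
        if lam is not None and blk.free_rows.any():
            E = GL @ omega                               # (n, 2)
            grad[k + 3] += 2.0 * float(np.sum(E[blk.free_rows, 0]))
            grad[k + 4] += 2.0 * float(np.sum(E[blk.free_rows, 1]))
    return n2ll, grad


def stacked_loglik_at(blocks: List[LayoutBlock], beta, sigmas, omega,
                      lam=None) -> float:
    """Exact marginal log-likelihood at fixed parameter values."""
    beta = np.asarray(beta, float)
    sigmas = np.asarray(sigmas, float)
    omega = np.asarray(omega, float)
    with_re = not np.allclose(omega, 0.0)
    total = 0.0
    for blk in blocks:
        Sg, n, _ = blk.X.shape
        V = np.diag(sigmas[blk.rtype] ** 2)
        if with_re:
            L = blk.L
            if lam is not None and blk.free_rows.any():
                L = L.copy()
                L[blk.free_rows] = np.asarray(lam, float)
            V = V + L @ omega @ L.T
        cho = linalg.cho_factor(V, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        resid = blk.y - np.einsum("snp,p->sn", blk.X, beta)
        rw = linalg.cho_solve(cho, resid.T)
        total += -0.5 * (Sg * (n * _LOG2PI + logdet) + float(np.sum(resid.T * rw)))
    return total


def _fit_no_re(blocks: List[LayoutBlock], n_rtypes: int) -> StackedFit:
    # V diagonal: GLS decouples; two-step weighted LS gives exact ML because
    # each fixed-effect column loads on a single residual type here.
    Xf = np.concatenate([blk.X.reshape(-1, blk.X.shape[2]) for blk in blocks])
    yf = np.concatenate([blk.y.reshape(-1) for blk in blocks])
    rt = np.concatenate([np.tile(blk.rtype, blk.X.shape[0]) for blk in blocks])
    p = Xf.shape[1]
    sigmas = np.ones(n_rtypes)
    beta = np.zeros(p)
    A = np.zeros((p, p))
    for it in range(2):
        w = np.ones(len(yf)) if it == 0 else 1.0 / sigmas[rt] ** 2
        A = (Xf * w[:, None]).T @ Xf
        beta = np.linalg.solve(A, (Xf * w[:, None]).T @ yf)
        res = yf - Xf @ beta
        for j in range(n_rtypes):
            m = rt == j
            sigmas[j] = np.sqrt(max(np.mean(res[m] ** 2), 1e-300))
    ll = 0.0
    res = yf - Xf @ beta
    for j in range(n_rtypes):
        m = rt == j
        ll += (-0.5 * m.sum() * (_LOG2PI + 2 * np.log(sigmas[j]))
               - 0.5 * np.sum(res[m] ** 2) / sigmas[j] ** 2)
    n_subj = sum(blk.X.shape[0] for blk in blocks)
    return StackedFit(beta=beta, cov_beta=np.linalg.inv(A), sigmas=sigmas,
                      omega=np.zeros((2, 2)), loglik=ll, converged=True,
                      n_obs=len(yf), n_subjects=n_subj)


def _moment_start(blocks: List[LayoutBlock], n_rtypes: int, has_free: bool):
    """Warm start from per-subject mean residuals of the no-RE fit.

    Subject-level means of the residuals on mu- and nu-loaded rows estimate
    the realized intercepts; their covariance (noise-corrected) seeds Omega,
    and a regression of the initial-condition residuals on them seeds the
    free loadings.
    """
    start = _fit_no_re(blocks, n_rtypes)
    mu_s, nu_s, x0_res = [], [], []
    var_noise = np.zeros(2)
    n_load = np.zeros(2)
    for blk in blocks:
        resid = blk.y - np.einsum("snp,p->sn", blk.X, start.beta)
        m_mu = (blk.L[:, 0] == 1.0) & ~blk.free_rows
        m_nu = (blk.L[:, 1] == 1.0) & ~blk.free_rows
        if m_mu.any():
            mu_s.append(resid[:, m_mu].mean(axis=1))
            var_noise[0] = np.mean(start.sigmas[blk.rtype[m_mu]] ** 2) / m_mu.sum()
        if m_nu.any():
            nu_s.append(resid[:, m_nu].mean(axis=1))
            var_noise[1] = np.mean(start.sigmas[blk.rtype[m_nu]] ** 2) / m_nu.sum()
        if blk.free_rows.any():
            x0_res.append(resid[:, blk.free_rows].mean(axis=1))
    mu_s = np.concatenate(mu_s) if mu_s else np.zeros(1)
    nu_s = np.concatenate(nu_s) if nu_s else np.zeros(len(mu_s))
    if len(nu_s) != len(mu_s):
        nu_s = np.zeros(len(mu_s))
    w1 = max(np.var(mu_s) - var_noise[0], 1e-3)
    w2 = max(np.var(nu_s) - var_noise[1], 1e-3)
    cov = float(np.cov(mu_s, nu_s)[0, 1]) if len(mu_s) > 1 else 0.0
    rho = np.clip(cov / np.sqrt(w1 * w2), -0.9, 0.9)
    l11 = np.sqrt(w1)
    l21 = rho * np.sqrt(w2)
    l22 = np.sqrt(max(w2 - l21 ** 2, 1e-4))
    lam0 = np.zeros(2)
    if has_free and x0_res:
        xr = np.concatenate(x0_res)
        U = np.column_stack([mu_s, nu_s])
        try:
            lam0 = np.linalg.lstsq(U, xr, rcond=None)[0]
        except np.linalg.LinAlgError:
            pass
        lam0 = np.clip(lam0, -20, 20)
    # subtract the random-effect share from the raw residual variances
    omega0 = np.array([[w1, l21 * l11], [l21 * l11, l21 ** 2 + l22 ** 2]])
    sig2 = start.sigmas ** 2
    for blk in blocks:
        for j in range(n_rtypes):
            rows = np.where(blk.rtype == j)[0]
            if not len(rows):
                continue
            L = lam0 if blk.free_rows[rows[0]] else blk.L[rows[0]]
            sig2[j] = max(start.sigmas[j] ** 2 - float(L @ omega0 @ L),
                          0.05 * start.sigmas[j] ** 2)
    return np.concatenate([
        0.5 * np.log(np.maximum(sig2, 1e-6)),
        [np.log(l11), np.log(l22), l21],
    ] + ([lam0] if has_free else []))


def fit_stacked_lmm(blocks: List[LayoutBlock], n_rtypes: int, with_re: bool,
                    x0: Optional[np.ndarray] = None,
                    diag_omega: bool = False) -> StackedFit:
    """Maximize the exact marginal likelihood of the stacked system.

    ``diag_omega`` constrains the random-intercept covariance to be
    diagonal (independent intercepts), which severs the only channel by
    which the cross-lag equation can inform the contemporaneous effect.
    """
    if not with_re:
        return _fit_no_re(blocks, n_rtypes)

    has_free = any(blk.free_rows.any() for blk in blocks)
    if x0 is None:
        x0 = _moment_start(blocks, n_rtypes, has_free)
        if diag_omega:
            x0[n_rtypes + 2] = 0.0

    l21_idx = n_rtypes + 2

    def obj(phi):
        if diag_omega:
            phi = phi.copy()
            phi[l21_idx] = 0.0
        val, grad = _stacked_neg2ll_grad(phi, blocks, n_rtypes)
        if diag_omega:
            grad = grad.copy()
            grad[l21_idx] = 0.0
        return val, grad

    res = optimize.minimize(obj, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    best = res
    if not res.success:
        def obj_plain(ph):
            if diag_omega:
                ph = ph.copy()
                ph[l21_idx] = 0.0
            return _stacked_neg2ll(ph, blocks, n_rtypes, True)[0]
        res2 = optimize.minimize(obj_plain, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8})
        if res2.fun <= res.fun:
            best = res2
    xbest = best.x.copy()
    if diag_omega:
        xbest[l21_idx] = 0.0
    n2ll, beta, A, sigmas, omega = _stacked_neg2ll(xbest, blocks, n_rtypes, True)
    converged = bool(best.success) and np.isfinite(n2ll)
    n_subj = sum(blk.X.shape[0] for blk in blocks)
    n_obs = sum(blk.X.shape[0] * blk.X.shape[1] for blk in blocks)
    lam = best.x[n_rtypes + 3:n_rtypes + 5] if has_free else None
    return StackedFit(beta=beta, cov_beta=np.linalg.inv(A), sigmas=sigmas,
                      omega=omega, loglik=-0.5 * n2ll, converged=converged,
                      n_obs=n_obs, n_subjects=n_subj, lam=lam)
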