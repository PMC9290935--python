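"""Exact marginal likelihood for the errors-in-variables dynamical model.

The latent-variable extension treats the true series ``X'`` and ``Y'`` as
unobserved, with observations ``X_obs = X' + theta`` and ``Y_obs = Y' + eta``
carrying known Gaussian measurement-error variances.  Conditional on the
observed third variable ``Z`` (measured without error) the latent system is
*linear* Gaussian even for the density / group-living structures, because
the auto-lag product ``f * Z[t-1] * X'[t-1]`` has a known time-varying
coefficient ``f * Z[t-1]``.  The per-subject state

    alpha[t] = (X'[t], Y'[t], mu_s, nu_s)

therefore follows a time-varying linear Gaussian state-space model, and a
Kalman filter (batched across subjects, scalar sequential measurement
updates) returns the exact marginal log-likelihood with the random
intercepts and latent series integrated out analytically.

Initial state: for the trade-off structure the transition is
time-invariant and the exact stationary joint distribution of
``(X'_1, Y'_1, mu, nu)`` is available in closed form.  For the Z-carrying
structures no closed form exists (the product process has no Gaussian
stationary law), so the first latent X is given a free initial-condition
model -- free mean, free loadings on the random intercepts and a free SD
-- and ``Y'_1 = a + b X'_1 + mu + eps_1`` follows exactly.  Ignoring the
correlation between the first state and the intercepts would bias the
contemporaneous effect, exactly as it does in the fully observed model.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

_LOG2PI = np.log(2.0 * np.pi)

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _filter_core(Xo, Yo, Z, has_z, z_load, m0, P0, a, b, c, d, f, e_nu, g,
                 sl2, vx, vy, q11, q12, q22):
    """Scalar-loop Kalman filter over all subjects; returns -2 loglik."""
    S, T = Xo.shape
    n2ll = 0.0
    m = np.empty(4)
    P = np.empty((4, 4))
    Pt1 = np.empty(4)
    W = np.empty((4, 4))
    Wt1 = np.empty(4)
    K = np.empty(4)
    for s in range(S):
        for i in range(4):
            m[i] = m0[i]
            for j in range(4):
                P[i, j] = P0[i, j]
        for t in range(T):
            if t > 0:
                phi = f * Z[s, t - 1] if has_z else 0.0
                mx = phi * m[0] + d * m[1] + e_nu * m[3] + c
                my = b * mx + m[2] + a
                m[0] = mx
                m[1] = my
                # W = T P with T rows t1=(phi,d,0,e_nu), b*t1+e_mu, e_mu, e_nu
                for j in range(4):
                    Pt1[j] = phi * P[0, j] + d * P[1, j] + e_nu * P[3, j]
                for j in range(4):
                    W[0, j] = Pt1[j]
                    W[1, j] = b * Pt1[j] + P[2, j]
                    W[2, j] = P[2, j]
                    W[3, j] = P[3, j]
                for i in range(4):
                    Wt1[i] = phi * W[i, 0] + d * W[i, 1] + e_nu * W[i, 3]
                for i in range(4):
                    P[i, 0] = Wt1[i]
                    P[i, 1] = b * Wt1[i] + W[i, 2]
                    P[i, 2] = W[i, 2]
                    P[i, 3] = W[i, 3]
                P[0, 0] += q11
                P[0, 1] += q12
                P[1, 0] += q12
                P[1, 1] += q22
            # measurement updates: X_obs (state 0), Y_obs (state 1),
            # optionally Z (loading z_load on state 3, intercept g)
            n_obs = 3 if has_z else 2
            for jo in range(n_obs):
                if jo == 0:
                    v = Xo[s, t] - m[0]
                    Svar = P[0, 0] + vx
                    for i in range(4):
                        K[i] = P[i, 0]
                elif jo == 1:
                    v = Yo[s, t] - m[1]
                    Svar = P[1, 1] + vy
                    for i in range(4):
                        K[i] = P[i, 1]
                else:
                    v = Z[s, t] - (g + z_load * m[3])
                    Svar = z_load * z_load * P[3, 3] + sl2
                    for i in range(4):
                        K[i] = z_load * P[i, 3]
                if Svar <= 0.0:
                    return np.inf
                n2ll += _LOG2PI + np.log(Svar) + v * v / Svar
                for i in range(4):
                    K[i] = K[i] / Svar
                for i in range(4):
                    m[i] += K[i] * v
                # P -= K (P H)' : rank-1 update with PH = K * Svar
                for i in range(4):
                    for j in range(4):
                        P[i, j] -= K[i] * K[j] * Svar
    return n2ll


def _has_z(structure: str) -> bool:
    return structure in ("grouplive", "density")


def n_params(structure: str, with_re: bool) -> int:
    if _has_z(structure):
        # a b c d f g, 3 log-SDs, init: m0x + log s0 (+2 loadings with REs)
        return 11 + (3 + 2 if with_re else 0)
    return 6 + (3 if with_re else 0)


def _unpack(theta, structure, with_re):
    a, b, c, d = theta[0:4]
    i = 4
    if _has_z(structure):
        f, g = theta[4:6]
        i = 6
        sig_eps, sig_kappa, sig_lambda = np.exp(theta[i:i + 3])
        i += 3
    else:
        f = g = 0.0
        sig_eps, sig_kappa = np.exp(theta[i:i + 2])
        sig_lambda = 0.0
        i += 2
    if with_re:
        l11, l22, l21 = np.exp(theta[i]), np.exp(theta[i + 1]), theta[i + 2]
        Lc = np.array([[l11, 0.0], [l21, l22]])
        omega = Lc @ Lc.T
        i += 3
    else:
        omega = np.zeros((2, 2))
    if _has_z(structure):
        m0x = theta[i]
        s0 = np.exp(theta[i + 1])
        i += 2
        lx = theta[i:i + 2] if with_re else np.zeros(2)
    else:
        m0x, s0, lx = 0.0, 0.0, np.zeros(2)
    return (a, b, c, d, f, g, sig_eps, sig_kappa, sig_lambda, omega,
            m0x, s0, lx)


def _init_tradeoff(a, b, c, d, se, sk, omega, e_nu):
    """Exact stationary joint of (X', Y', mu, nu) for the trade-off."""
    A2 = np.array([[0.0, d], [0.0, b * d]])
    if abs(b * d) >= 0.999:
        return None, None
    k0 = np.array([c, a + b * c])
    m2 = np.linalg.solve(np.eye(2) - A2, k0)
    Q2 = np.array([[sk ** 2, b * sk ** 2],
                   [b * sk ** 2, b ** 2 * sk ** 2 + se ** 2]])
    try:
        Pinf = linalg.solve_discrete_lyapunov(A2, Q2)
    except Exception:
        return None, None
    B = np.array([[0.0, e_nu], [1.0, b * e_nu]])
    M = np.linalg.solve(np.eye(2) - A2, B)
    P0 = np.zeros((4, 4))
    P0[:2, :2] = Pinf + M @ omega @ M.T
    P0[:2, 2:] = M @ omega
    P0[2:, :2] = omega @ M.T
    P0[2:, 2:] = omega
    m0 = np.array([m2[0], m2[1], 0.0, 0.0])
    return m0, P0


def _init_free(a, b, se, omega, m0x, s0, lx):
    """Free initial-condition model: X'_1 = m0x + lx.(mu,nu) + delta."""
    Ol = omega @ lx                      # Cov(u, X'_1)
    cxx = float(lx @ Ol) + s0 ** 2
    cxu = Ol                             # (2,)
    cyx = b * cxx + cxu[0]
    cyy = (b ** 2 * cxx + omega[0, 0] + se ** 2
           + 2.0 * b * cxu[0])
    cyu = b * cxu + omega[0]             # Cov((mu,nu), Y'_1)
    P0 = np.zeros((4, 4))
    P0[0, 0] = cxx
    P0[0, 1] = P0[1, 0] = cyx
    P0[1, 1] = cyy
    P0[0, 2:] = P0[2:, 0] = cxu
    P0[1, 2:] = P0[2:, 1] = cyu
    P0[2:, 2:] = omega
    m0 = np.array([m0x, a + b * m0x, 0.0, 0.0])
    return m0, P0


def sem_plus_neg2ll(theta, Xo, Yo, Z, structure, vx, vy, with_re):
    """-2 log marginal likelihood of the observed panel.

    Xo, Yo : (S, T) observed (error-contaminated) series
    Z      : (S, T) observed third variable or None (trade-off)
    vx, vy : known measurement-error variances
    """
    (a, b, c, d, f, g, se, sk, sl, omega,
     m0x, s0, lx) = _unpack(theta, structure, with_re)
    S, T = Xo.shape
    tradeoff = structure == "tradeoff"
    e_nu = 1.0 if (tradeoff and with_re) else 0.0
    if np.max(np.abs(theta)) > 40:
        return np.inf

    if tradeoff:
        m0, P0 = _init_tradeoff(a, b, c, d, se, sk, omega, e_nu)
        if m0 is None:
            return np.inf
    else:
        m0, P0 = _init_free(a, b, se, omega, m0x, s0, lx)

    if _HAVE_NUMBA:
        Zc = Z if Z is not None else np.zeros((1, 1))
        return _filter_core(
            Xo, Yo, Zc, Z is not None, 1.0 if with_re else 0.0, m0, P0,
            a, b, c, d, f, e_nu, g, sl ** 2, vx, vy,
            sk ** 2, b * sk ** 2, b ** 2 * sk ** 2 + se ** 2)

    m = np.broadcast_to(m0, (S, 4)).copy()
    P = np.broadcast_to(P0, (S, 4, 4)).copy()

    Q = np.zeros((4, 4))
    Q[:2, :2] = np.array([[sk ** 2, b * sk ** 2],
                          [b * sk ** 2, b ** 2 * sk ** 2 + se ** 2]])
    cvec = np.array([c, a + b * c, 0.0, 0.0])

    obs_rows = [(np.array([1.0, 0.0, 0.0, 0.0]), 0.0, vx, Xo),
                (np.array([0.0, 1.0, 0.0, 0.0]), 0.0, vy, Yo)]
    if Z is not None:
        z_load = 1.0 if with_re else 0.0
        obs_rows.append((np.array([0.0, 0.0, 0.0, z_load]), g, sl ** 2, Z))

    n2ll = 0.0
    for t in range(T):
        if t > 0:
            # batched transition, exploiting the sparse structure: the
            # X'-row is t1 = (phi, d, 0, e_nu), the Y'-row is b*t1 + e_mu,
            # and the intercept rows are static
            phi = np.zeros(S) if tradeoff else f * Z[:, t - 1]
            mx = phi * m[:, 0] + d * m[:, 1] + e_nu * m[:, 3] + c
            my = b * mx + m[:, 2] + a
            m = np.stack([mx, my, m[:, 2], m[:, 3]], axis=1)
            # W = T P (rows): row1 = P t1, row2 = b*row1 + P[:,2]
            Pt1 = (P[:, :, 0] * phi[:, None] + P[:, :, 1] * d
                   + P[:, :, 3] * e_nu)                    # (S, 4) = P t1
            W = np.stack([Pt1, b * Pt1 + P[:, :, 2],
                          P[:, :, 2], P[:, :, 3]], axis=1)  # (S, 4, 4)
            Wt1 = (W[:, :, 0] * phi[:, None] + W[:, :, 1] * d
                   + W[:, :, 3] * e_nu)
            P = np.stack([Wt1, b * Wt1 + W[:, :, 2],
                          W[:, :, 2], W[:, :, 3]], axis=2) + Q
        for H, dconst, rvar, data in obs_rows:
            pred = m @ H + dconst
            v = data[:, t] - pred
            PH = P @ H                          # (S, 4)
            Svar = PH @ H + rvar                # (S,)
            if np.any(Svar <= 0):
                return np.inf
            K = PH / Svar[:, None]
            m = m + K * v[:, None]
            P = P - np.einsum("si,sj->sij", K, PH)
            P = 0.5 * (P + P.transpose(0, 2, 1))
            n2ll += float(np.sum(_LOG2PI + np.log(Svar) + v ** 2 / Svar))
    return n2ll
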