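"""Independent reference computations used by the test suite.

Everything here maximizes an explicitly-written likelihood with generic
scipy optimizers (or evaluates a closed form); none of it shares code with
the package's fitting paths.
"""

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special


def nb_glm_mle(y, X, offset=None):
    """Direct MLE of a plain NB GLM (log link) by BFGS on the exact
    log-likelihood; returns (beta, theta)."""
    y = np.asarray(y, dtype=float)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, float)

    def nll(par):
        b, lth = par[:-1], par[-1]
        th = np.exp(np.clip(lth, -10, 14))
        mu = np.exp(np.clip(offset + X @ b, -30, 30))
        ll = (special.gammaln(y + th) - special.gammaln(th)
              - special.gammaln(y + 1) + th * np.log(th)
              + y * np.log(mu) - (y + th) * np.log(th + mu))
        return -np.sum(ll)

    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    x0 = np.concatenate([glm.params, [np.log(2.0)]])
    res = optimize.minimize(nll, x0, method="BFGS")
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 5000, "fatol": 1e-12,
                                     "xatol": 1e-10})
    return res.x[:-1], float(np.exp(res.x[-1]))


def gh_nbmm_mle(y, X, groups, offset, theta, n_nodes=50):
    """Exact-marginal MLE of a random-intercept NBMM (known theta) by
    Gauss-Hermite quadrature over the subject effect; returns beta."""
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    ug = np.unique(groups)
    th = theta

    def nll(par):
        p = X.shape[1]
        b, lpsi = par[:p], np.clip(par[p], -12, 5)
        s = np.sqrt(2 * np.exp(lpsi))
        eta = offset + X @ b
        tot = 0.0
        for g in ug:
            m = groups == g
            lm = eta[m][:, None] + s * t[None, :]
            mu = np.exp(np.clip(lm, -30, 30))
            ll = (special.gammaln(y[m][:, None] + th) - special.gammaln(th)
                  - special.gammaln(y[m][:, None] + 1) + th * np.log(th)
                  + y[m][:, None] * lm - (y[m][:, None] + th) * np.log(th + mu))
            lw = ll.sum(0) + np.log(w) - 0.5 * np.log(np.pi)
            tot += special.logsumexp(lw)
        return -tot

    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    x0 = np.concatenate([glm.params, [np.log(0.3)]])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 8000, "xatol": 1e-9,
                                     "fatol": 1e-11})
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 8000, "xatol": 1e-9,
                                     "fatol": 1e-11})
    return res.x[: X.shape[1]]


def lmm_direct_mle(y, X, Z, groups, reml=False):
    """Brute-force random-intercept/slope LMM: numerically maximize the
    marginal Gaussian likelihood with per-subject covariance built
    explicitly; returns (beta, psi, sigma2, loglik)."""
    y = np.asarray(y, float)
    ug = np.unique(groups)
    n, p = X.shape
    q = Z.shape[1]
    ntri = q * (q + 1) // 2

    def build_psi(par):
        L = np.zeros((q, q))
        pos = 0
        for j in range(q):
            for i in range(j, q):
                L[i, j] = np.exp(np.clip(par[pos], -10, 8)) if i == j else par[pos]
                pos += 1
        return L @ L.T

    last = {}

    def nll(par):
        psi = build_psi(par[:ntri])
        s2 = np.exp(np.clip(par[ntri], -12, 12))
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        pieces = []
        for g in ug:
            m = groups == g
            V = Z[m] @ psi @ Z[m].T + s2 * np.eye(m.sum())
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e12
            Vi = np.linalg.inv(V)
            A += X[m].T @ Vi @ X[m]
            bvec += X[m].T @ Vi @ y[m]
            pieces.append((m, Vi, ld))
        beta = np.linalg.solve(A + 1e-12 * np.eye(p), bvec)
        tot = 0.0
        for m, Vi, ld in pieces:
            e = y[m] - X[m] @ beta
            tot += 0.5 * (ld + e @ Vi @ e + m.sum() * np.log(2 * np.pi))
        if reml:
            tot += 0.5 * np.linalg.slogdet(A)[1]
        last["beta"], last["psi"], last["s2"] = beta, psi, float(s2)
        return tot

    x0 = np.concatenate([np.full(ntri, -1.0), [np.log(np.var(y) + 1e-6)]])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10,
                                     "fatol": 1e-12})
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10,
                                     "fatol": 1e-12})
    nll(res.x)
    return last["beta"], last["psi"], last["s2"], -res.fun


def zig_direct_mle(y, X, p_const_start=0.3):
    """Direct MLE of a fixed-effects-only zero-inflated Gaussian model with
    intercept-only zero part, by Nelder-Mead on the observed likelihood."""
    y = np.asarray(y, float)
    n, p = X.shape

    def nll(par):
        b = par[:p]
        pz = 1.0 / (1.0 + np.exp(-par[p]))
        s2 = np.exp(np.clip(par[p + 1], -12, 12))
        mu = X @ b
        dens = np.exp(-0.5 * (y - mu) ** 2 / s2) / np.sqrt(2 * np.pi * s2)
        lik = np.where(y == 0, pz + (1 - pz) * dens, (1 - pz) * dens)
        return -np.sum(np.log(np.clip(lik, 1e-300, None)))

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    x0 = np.concatenate([beta0, [np.log(p_const_start / (1 - p_const_start)),
                                 np.log(max(np.var(y), 1e-3))]])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-9,
                                     "fatol": 1e-12})
    res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-9,
                                     "fatol": 1e-12})
    b = res.x[:p]
    return b, 1.0 / (1.0 + np.exp(-res.x[p])), float(np.exp(res.x[p + 1]))


def logistic_mle(xi, Z):
    """Direct MLE of a binomial model with fractional response by generic
    optimization of the Bernoulli-type log-likelihood."""
    xi = np.asarray(xi, float)

    def nll(a):
        eta = np.clip(Z @ a, -30, 30)
        return -np.sum(xi * eta - np.log1p(np.exp(eta)))

    res = optimize.minimize(nll, np.zeros(Z.shape[1]), method="BFGS")
    return res.x
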