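"""Weighted linear mixed model solver.

This is the inner engine behind every outer algorithm in the package: the
penalized-quasi-likelihood loops for count models and the M-steps of the
zero-inflated EM fitters all reduce to fitting a Gaussian linear mixed model
to a working response with prior observation weights.

Model, per subject i:

    y_i = offset_i + X_i beta + Z_i b_i + e_i
    b_i ~ N(0, Psi),   e_i ~ N(0, sigma^2 W_i^{-1/2} R_i W_i^{-1/2})

with W_i the diagonal of prior weights and R_i an optional within-subject
correlation matrix (AR(1) on observation order, or compound symmetry).

Estimation profiles beta and sigma^2 out of the (restricted) Gaussian
likelihood and optimizes the remaining variance parameters on an
unconstrained scale: the log-Cholesky factor of D = Psi / sigma^2 and
atanh(rho).  The parameterization keeps Psi positive semi-definite and
|rho| < 1 by construction; a Psi that collapses to the boundary is reported,
not errored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LMMProblem",
    "LMMFit",
    "fit_weighted_lmm",
    "wald_table",
    "ar1_correlation_matrix",
    "cs_correlation_matrix",
]

_LOGDIAG_LO, _LOGDIAG_HI = -12.0, 8.0
_RHO_BOUND = 6.0  # atanh scale; |rho| < tanh(6) ~ 0.99999


def ar1_correlation_matrix(times_or_order, rho: float) -> np.ndarray:
    """AR(1) correlation: entry (j,k) = rho^|pos_j - pos_k|.

    Positions are within-subject observation order (discrete lags), not
    continuous time gaps.
    """
    if abs(rho) >= 1:
        raise ValueError("AR(1) requires |rho| < 1")
    pos = np.asarray(times_or_order, dtype=float)
    lag = np.abs(pos[:, None] - pos[None, :])
    return rho ** lag if rho != 0 else (lag == 0).astype(float)


def cs_correlation_matrix(n: int, rho: float) -> np.ndarray:
    """Compound symmetry: constant off-diagonal correlation rho."""
    if abs(rho) >= 1:
        raise ValueError("compound symmetry requires |rho| < 1")
    return np.full((n, n), rho) + (1.0 - rho) * np.eye(n)


@dataclass
class LMMProblem:
    """One weighted LMM instance on grouped data.

    ``Z`` may be ``None`` for a fixed-effects-only (GLS/WLS) fit.  Rows must
    be grouped contiguously by ``groups``; ``order`` gives the within-group
    observation positions used by the AR(1) structure.
    """

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray
    Z: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    offset: Optional[np.ndarray] = None
    correlation: str = "none"
    order: Optional[np.ndarray] = None
    x_names: Optional[list[str]] = None
    z_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("prior weights must be strictly positive")
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float)
        if self.Z is not None:
            self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.groups = np.asarray(self.groups)
        if self.order is None:
            self.order = _default_order(self.groups)
        if self.correlation not in ("none", "ar1", "cs"):
            raise ValueError(f"unknown correlation {self.correlation!r}")

    @property
    def q(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]


@dataclass
class LMMFit:
    """Estimates from one weighted LMM fit."""

    beta: np.ndarray
    beta_cov: np.ndarray
    psi: np.ndarray             # random-effect covariance (sigma^2 * D)
    sigma2: float
    rho: float
    loglik: float
    fitted: np.ndarray          # conditional means offset + X beta + Z bhat
    ranef: Optional[np.ndarray] = None    # BLUPs, n_groups x q
    converged: bool = True
    n_iter: int = 0
    varparams: Optional[np.ndarray] = None   # internal unconstrained optimum
    x_names: Optional[list[str]] = None
    aliased: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    method: str = "REML"


def _default_order(groups) -> np.ndarray:
    order = np.zeros(len(groups), dtype=int)
    _, start = np.unique(groups, return_index=True)
    for s in start:
        g = groups[s]
        idx = np.flatnonzero(groups == g)
        order[idx] = np.arange(len(idx))
    return order


# ---------------------------------------------------------------------------
# bucketed (group-size batched) likelihood machinery
# ---------------------------------------------------------------------------

class _Buckets:
    """Groups stacked by common size so per-group linear algebra batches."""

    def __init__(self, prob: LMMProblem):
        groups = prob.groups
        uniq, first = np.unique(groups, return_index=True)
        uniq = uniq[np.argsort(first)]  # preserve appearance order
        idx_by_group = [np.flatnonzero(groups == g) for g in uniq]
        sizes = np.array([len(ix) for ix in idx_by_group])
        self.n_groups = len(uniq)
        self.buckets = []
        r = prob.y - prob.offset
        s = 1.0 / np.sqrt(prob.weights)
        for k in np.unique(sizes):
            sel = [ix for ix in idx_by_group if len(ix) == k]
            rows = np.stack(sel)                      # (G, k)
            b = {
                "rows": rows,
                "X": prob.X[rows],                    # (G, k, p)
                "r": r[rows],                         # (G, k)
                "s": s[rows],                         # (G, k)
                "pos": prob.order[rows].astype(float),
            }
            if prob.Z is not None:
                b["Z"] = prob.Z[rows]                 # (G, k, q)
            if prob.correlation == "ar1":
                b["lag"] = np.abs(b["pos"][:, :, None] - b["pos"][:, None, :])
            self.buckets.append(b)


def _unpack_params(theta: np.ndarray, q: int, has_rho: bool):
    """theta -> (D = L L' with log-diagonal Cholesky, rho)."""
    ntri = q * (q + 1) // 2
    D = None
    if q:
        L = np.zeros((q, q))
        pos = 0
        for j in range(q):
            for i in range(j, q):
                v = theta[pos]
                L[i, j] = np.exp(np.clip(v, _LOGDIAG_LO, _LOGDIAG_HI)) if i == j else v
                pos += 1
        D = L @ L.T
    rho = float(np.tanh(theta[ntri])) if has_rho else 0.0
    return D, rho


def _pack_init(q: int, has_rho: bool, diag: float) -> np.ndarray:
    ntri = q * (q + 1) // 2
    theta = np.zeros(ntri + int(has_rho))
    pos = 0
    for j in range(q):
        for i in range(j, q):
            if i == j:
                theta[pos] = diag
            pos += 1
    return theta


def _profile_nll(theta, buckets: _Buckets, q, has_rho, correlation, N, p, reml):
    """Negative profiled (restricted) log-likelihood; beta, sigma^2 profiled out."""
    D, rho = _unpack_params(theta, q, has_rho)
    XtViX = np.zeros((p, p))
    XtVir = np.zeros(p)
    rtVir = 0.0
    logdet = 0.0
    for b in buckets.buckets:
        G, k, _ = b["X"].shape
        sw = b["s"]
        if correlation == "ar1":
            R = np.where(b["lag"] == 0, 1.0, rho ** b["lag"]) if rho != 0 else \
                np.broadcast_to(np.eye(k), (G, k, k))
        elif correlation == "cs":
            R = np.broadcast_to(np.full((k, k), rho) + (1 - rho) * np.eye(k), (G, k, k))
        else:
            R = np.broadcast_to(np.eye(k), (G, k, k))
        C = R * sw[:, :, None] * sw[:, None, :]
        if q:
            V = b["Z"] @ D @ b["Z"].transpose(0, 2, 1) + C
        else:
            V = np.ascontiguousarray(C)
        sign, ld = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            return 1e12
        logdet += ld.sum()
        rhs = np.concatenate([b["X"], b["r"][:, :, None]], axis=2)
        try:
            sol = np.linalg.solve(V, rhs)
        except np.linalg.LinAlgError:
            return 1e12
        ViX, Vir = sol[:, :, :p], sol[:, :, p]
        XtViX += np.einsum("gkp,gkq->pq", b["X"], ViX)
        XtVir += np.einsum("gkp,gk->p", b["X"], Vir)
        rtVir += float(np.einsum("gk,gk->", b["r"], Vir))
    try:
        cf = np.linalg.cholesky(XtViX + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        return 1e12
    beta = np.linalg.solve(XtViX + 1e-12 * np.eye(p), XtVir)
    qform = max(rtVir - beta @ XtVir, 1e-300)
    df = N - p if reml else N
    sigma2 = qform / df
    nll = 0.5 * (df * np.log(sigma2) + logdet + df)
    if reml:
        nll += float(np.log(np.diag(cf)).sum())
    if not np.isfinite(nll):
        return 1e12
    return nll


def _solve_at(theta, prob: LMMProblem, buckets: _Buckets, reml: bool):
    """Full solution (beta, covariances, BLUPs, fitted) at given varparams."""
    q, p = prob.q, prob.X.shape[1]
    has_rho = prob.correlation != "none"
    D, rho = _unpack_params(theta, q, has_rho)
    N = len(prob.y)
    XtViX = np.zeros((p, p))
    XtVir = np.zeros(p)
    rtVir = 0.0
    logdet = 0.0
    pieces = []
    for b in buckets.buckets:
        G, k, _ = b["X"].shape
        sw = b["s"]
        if prob.correlation == "ar1":
            R = np.where(b["lag"] == 0, 1.0, rho ** b["lag"]) if rho != 0 else \
                np.broadcast_to(np.eye(k), (G, k, k))
        elif prob.correlation == "cs":
            R = np.broadcast_to(np.full((k, k), rho) + (1 - rho) * np.eye(k), (G, k, k))
        else:
            R = np.broadcast_to(np.eye(k), (G, k, k))
        C = R * sw[:, :, None] * sw[:, None, :]
        V = (b["Z"] @ D @ b["Z"].transpose(0, 2, 1) + C) if q else np.ascontiguousarray(C)
        sign, ld = np.linalg.slogdet(V)
        logdet += ld.sum()
        rhs = np.concatenate([b["X"], b["r"][:, :, None]], axis=2)
        sol = np.linalg.solve(V, rhs)
        ViX, Vir = sol[:, :, :p], sol[:, :, p]
        XtViX += np.einsum("gkp,gkq->pq", b["X"], ViX)
        XtVir += np.einsum("gkp,gk->p", b["X"], Vir)
        rtVir += float(np.einsum("gk,gk->", b["r"], Vir))
        pieces.append((b, V))
    XtViX_reg = XtViX + 1e-12 * np.eye(p)
    beta = np.linalg.solve(XtViX_reg, XtVir)
    qform = max(rtVir - beta @ XtVir, 1e-300)
    df = N - p if reml else N
    sigma2 = qform / df
    beta_cov = sigma2 * np.linalg.inv(XtViX_reg)
    loglik = -0.5 * (df * np.log(sigma2) + logdet + df + df * np.log(2 * np.pi))
    if reml:
        sign, ldx = np.linalg.slogdet(XtViX_reg)
        loglik -= 0.5 * ldx

    fitted = prob.offset + prob.X @ beta
    ranef = None
    if q:
        uniq, first = np.unique(prob.groups, return_index=True)
        code_index = {c: i for i, c in enumerate(uniq[np.argsort(first)])}
        ranef = np.zeros((buckets.n_groups, q))
        for b, V in pieces:
            e = b["r"] - b["X"] @ beta
            Vie = np.linalg.solve(V, e[:, :, None])[:, :, 0]
            bhat = np.einsum("gkq,gk->gq", b["Z"], Vie) @ D.T
            rows = b["rows"]
            contrib = np.einsum("gkq,gq->gk", b["Z"], bhat)
            fitted[rows.ravel()] += contrib.ravel()
            for g in range(rows.shape[0]):
                ranef[code_index[prob.groups[rows[g, 0]]]] = bhat[g]
    psi = sigma2 * D if q else np.zeros((0, 0))
    return beta, beta_cov, psi, sigma2, rho, loglik, fitted, ranef


def _drop_aliased(X: np.ndarray, names):
    """Identify linearly dependent columns via QR with column pivoting."""
    n, p = X.shape
    if p == 0:
        return X, list(range(p)), []
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Q, R, piv = _qr_pivot(X / scale)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[j] if names else str(j) for j in sorted(piv[rank:])]
    return X[:, keep], keep, dropped


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _mom_start(prob: LMMProblem, keep_X: np.ndarray) -> float:
    """Method-of-moments guess for the relative random-intercept scale."""
    r = prob.y - prob.offset
    beta, *_ = np.linalg.lstsq(keep_X, r, rcond=None)
    resid = r - keep_X @ beta
    total = resid.var() + 1e-12
    gm = pd.Series(resid).groupby(pd.Series(prob.groups)).mean()
    between = gm.var() if len(gm) > 1 else 0.0
    ratio = np.clip(between / total, 1e-4, 1e2)
    return 0.5 * np.log(ratio)


def fit_weighted_lmm(
    problem: LMMProblem,
    method: str = "REML",
    start: Optional[np.ndarray] = None,
    maxiter: int = 200,
) -> LMMFit:
    """Fit the weighted LMM by quasi-Newton optimization of the profiled
    (restricted) likelihood.

    Non-convergence of the variance-component optimizer yields a flagged
    fit (``converged=False`` with a warning), never an exception; singular
    fixed-effect designs have aliased columns dropped with a warning.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    reml = method == "REML"
    warns: list[str] = []

    names = problem.x_names or [f"x{j}" for j in range(problem.X.shape[1])]
    Xk, keep, dropped = _drop_aliased(problem.X, names)
    if dropped:
        warns.append(f"aliased columns dropped: {', '.join(dropped)}")
        problem = LMMProblem(
            y=problem.y, X=Xk, groups=problem.groups, Z=problem.Z,
            weights=problem.weights, offset=problem.offset,
            correlation=problem.correlation, order=problem.order,
            x_names=[names[j] for j in keep], z_names=problem.z_names,
        )
        names = problem.x_names

    n_groups = len(np.unique(problem.groups))
    q = problem.q
    has_rho = problem.correlation != "none"
    N, p = problem.X.shape
    buckets = _Buckets(problem)

    nparams = q * (q + 1) // 2 + int(has_rho)
    if nparams == 0:
        # pure (weighted) GLS: closed form, nothing to optimize
        theta = np.zeros(0)
        out = _solve_at(theta, problem, buckets, reml)
        return _make_fit(out, theta, True, 0, names, dropped, warns, method)

    if q and n_groups < 2:
        raise ValueError("random effects require at least 2 subjects")

    obj = lambda th: _profile_nll(th, buckets, q, has_rho, problem.correlation,
                                  N, p, reml)
    starts = []
    if start is not None and len(start) == nparams:
        starts.append(np.asarray(start, dtype=float))
    starts.append(_pack_init(q, has_rho, _mom_start(problem, problem.X) if q else 0.0))
    starts.append(_pack_init(q, has_rho, -4.0))

    bounds = []
    pos = 0
    for j in range(q):
        for i in range(j, q):
            bounds.append((_LOGDIAG_LO, _LOGDIAG_HI) if i == j else (-30.0, 30.0))
            pos += 1
    if has_rho:
        bounds.append((-_RHO_BOUND, _RHO_BOUND))

    best = None
    converged = False
    n_iter = 0
    for k, x0 in enumerate(starts):
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            if k >= 1 or start is not None:
                break  # warm/MoM start succeeded; no need for more restarts
    if not converged:
        warns.append("variance-component optimizer did not converge; "
                     "returning best point found")

    theta = best.x
    D, _ = _unpack_params(theta, q, has_rho)
    if q and np.trace(D) < 1e-8:
        warns.append("random-effect covariance at boundary (Psi ~ 0)")
    out = _solve_at(theta, problem, buckets, reml)
    return _make_fit(out, theta, converged, n_iter, names, dropped, warns, method)


def _make_fit(out, theta, converged, n_iter, names, dropped, warns, method) -> LMMFit:
    beta, beta_cov, psi, sigma2, rho, loglik, fitted, ranef = out
    return LMMFit(
        beta=beta, beta_cov=beta_cov, psi=psi, sigma2=sigma2, rho=rho,
        loglik=loglik, fitted=fitted, ranef=ranef, converged=converged,
        n_iter=n_iter, varparams=theta, x_names=names, aliased=dropped,
        warnings=warns, method=method,
    )


def wald_table(
    fit: LMMFit,
    df: Optional[float] = None,
) -> pd.DataFrame:
    """Per-coefficient Wald tests.

    Two-sided p-values from a standard normal reference by default, or a
    t(df) reference when ``df`` is given (an nlme-style approximation
    df = N - n_subjects - rank(X) + 1 can be supplied by the caller).
    A zero standard error with a nonzero estimate yields p = 0 with a
    warning.
    """
    se = np.sqrt(np.clip(np.diag(fit.beta_cov), 0.0, None))
    est = fit.beta
    stat = np.full_like(est, 0.0)
    pvals = np.ones_like(est)
    for j in range(len(est)):
        if se[j] == 0:
            if est[j] != 0:
                warnings.warn("zero standard error with nonzero estimate; p-value set to 0")
                stat[j], pvals[j] = np.inf, 0.0
            else:
                stat[j], pvals[j] = 0.0, 1.0
        else:
            stat[j] = est[j] / se[j]
            if df is None:
                pvals[j] = 2.0 * stats.norm.sf(abs(stat[j]))
            else:
                pvals[j] = 2.0 * stats.t.sf(abs(stat[j]), df)
    names = fit.x_names or [f"x{j}" for j in range(len(est))]
    return pd.DataFrame(
        {"estimate": est, "se": se, "statistic": stat, "pvalue": pvals},
        index=names,
    )
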