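"""Negative binomial mixed models fitted by iterative weighted least squares.

The count model for taxon h is

    C_ij ~ NB(mu_ij, theta),   log mu_ij = log(T_ij) + X_ij beta + Z_ij b_i,
    b_i ~ N(0, Psi)

with NB variance mu + mu^2/theta, so theta -> infinity recovers the Poisson.
Fitting alternates two steps until the fixed effects and log(theta)
stabilize:

1. a penalized-quasi-likelihood step: linearize the log link around the
   current conditional means to obtain the working response
   z = eta - offset + (y - mu)/mu with weights w = mu*theta/(theta + mu),
   and fit the weighted linear mixed model of :mod:`mbmm.lmm` to z;
2. a Newton-Raphson update of theta on the NB profile log-likelihood at the
   current fitted means.

Standard errors for the fixed effects come from the final weighted LMM
(PQL-style); no sandwich correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .data import DesignBundle, FitResult
from .lmm import LMMFit, LMMProblem, fit_weighted_lmm, wald_table

__all__ = [
    "FitControl",
    "nb_working_response_and_weights",
    "update_theta_newton",
    "nb_loglik_theta",
    "fit_nbmm",
]

_THETA_LO, _THETA_HI = 1e-3, 1e5
_MU_LO, _MU_HI = 1e-8, 1e8


@dataclass
class FitControl:
    """Convergence control shared by the outer fitting loops."""

    tol: float = 1e-5
    max_outer: int = 50
    em_tol: float = 1e-4
    max_em: int = 100
    inner_sweeps: int = 5       # IWLS sweeps per EM M-step
    lmm_method: str = "REML"
    wald_df: Optional[float] = None
    fix_theta: Optional[float] = None   # hold the NB dispersion fixed


def nb_working_response_and_weights(y, eta, mu, theta, offset=None):
    """GLM working quantities for the NB log link.

    z = (eta - offset) + (y - mu)/mu,  w = mu * theta / (theta + mu)
    (w = mu^2 / V(mu) with V(mu) = mu + mu^2/theta).
    """
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_LO, _MU_HI)
    if offset is None:
        offset = 0.0
    z = (eta - offset) + (y - mu) / mu
    w = mu * theta / (theta + mu)
    return z, w


def nb_loglik_theta(theta, y, mu, weights=None) -> float:
    """NB log-likelihood in theta with means held fixed (terms in theta only
    would suffice; the full per-observation likelihood is returned)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    ll = (special.gammaln(y + theta) - special.gammaln(theta)
          - special.gammaln(y + 1.0)
          + theta * np.log(theta) + y * np.log(np.clip(mu, 1e-300, None))
          - (y + theta) * np.log(theta + mu))
    return float(np.sum(w * ll))


def update_theta_newton(y, mu, theta0, weights=None, max_steps: int = 25,
                        tol: float = 1e-8) -> float:
    """Newton-Raphson update of the NB dispersion at fixed means.

    Iterates on the score of the profile log-likelihood

        l(theta) = sum [ lnGamma(y+theta) - lnGamma(theta) + theta ln theta
                         - (y+theta) ln(theta+mu) + y ln mu ]

    clipped to [1e-3, 1e5].  A non-finite score triggers a bounded
    golden-section style search on l(theta) instead (with a warning).
    """
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_LO, _MU_HI)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    theta = float(np.clip(theta0, _THETA_LO, _THETA_HI))

    def score_info(th):
        sc = np.sum(w * (special.digamma(y + th) - special.digamma(th)
                         + np.log(th) + 1.0 - np.log(th + mu)
                         - (y + th) / (th + mu)))
        info = np.sum(w * (special.polygamma(1, y + th) - special.polygamma(1, th)
                           + 1.0 / th - 2.0 / (th + mu)
                           + (y + th) / (th + mu) ** 2))
        return sc, info

    for _ in range(max_steps):
        sc, info = score_info(theta)
        if not np.isfinite(sc) or not np.isfinite(info):
            warnings.warn("non-finite dispersion score; falling back to bounded search")
            res = optimize.minimize_scalar(
                lambda lt: -nb_loglik_theta(np.exp(lt), y, mu, w),
                bounds=(np.log(_THETA_LO), np.log(_THETA_HI)), method="bounded",
            )
            return float(np.clip(np.exp(res.x), _THETA_LO, _THETA_HI))
        if info >= 0:
            # not locally concave: take a damped score step on log scale
            step = np.sign(sc) * 0.5
        else:
            step = -sc / info / max(theta, 1e-10)  # convert to log-scale-ish step
            step = np.clip(step, -2.0, 2.0)
        new = float(np.clip(theta * np.exp(step), _THETA_LO, _THETA_HI))
        if abs(np.log(new) - np.log(theta)) < tol:
            theta = new
            break
        theta = new
    return theta


def _init_mu_theta(y, X, offset):
    """Poisson GLM initialization: mu from the GLM fit, theta by moments on
    the Pearson residuals."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
            res = glm.fit(maxiter=50)
        mu0 = np.clip(res.mu, _MU_LO, _MU_HI)
    except Exception:
        mu0 = np.clip(np.exp(offset) * (y.mean() / max(np.exp(offset).mean(), 1e-300)
                                        if np.any(offset) else max(y.mean(), 0.5)),
                      _MU_LO, _MU_HI)
        if np.isscalar(mu0) or mu0.ndim == 0:
            mu0 = np.full_like(y, float(mu0), dtype=float)
    excess = np.sum((y - mu0) ** 2 - mu0)
    denom = np.sum(mu0 ** 2)
    theta0 = _THETA_HI if excess <= 0 else float(np.clip(denom / excess, _THETA_LO, _THETA_HI))
    return mu0, theta0


@dataclass
class _PQLState:
    eta: np.ndarray
    mu: np.ndarray
    theta: float
    lmm_fit: Optional[LMMFit] = None
    varparams: Optional[np.ndarray] = None
    n_sweeps: int = 0
    converged: bool = False
    warnings: list[str] = field(default_factory=list)


def _pql_sweeps(
    y, design: DesignBundle, state: _PQLState, control: FitControl,
    prior_weights=None, max_sweeps: Optional[int] = None, update_theta: bool = True,
) -> _PQLState:
    """Run IWLS sweeps from ``state``; each sweep = working LMM fit + one
    Newton dispersion update.  Used both by :func:`fit_nbmm` (to
    convergence) and as the capped M-step of the zero-inflated EM."""
    pw = np.ones_like(y, dtype=float) if prior_weights is None else prior_weights
    max_sweeps = control.max_outer if max_sweeps is None else max_sweeps
    if control.fix_theta is not None:
        state.theta = float(control.fix_theta)
        update_theta = False
    beta_prev = None
    for sweep in range(max_sweeps):
        z, w = nb_working_response_and_weights(y, state.eta, state.mu,
                                              state.theta, design.offset)
        w_tot = np.clip(w * pw, 1e-10, None)
        prob = LMMProblem(
            y=z, X=design.X, groups=design.groups, Z=design.Z,
            weights=w_tot, offset=None, correlation=design.correlation,
            order=design.order, x_names=design.x_names, z_names=design.z_names,
        )
        fit = fit_weighted_lmm(prob, method=control.lmm_method,
                               start=state.varparams)
        state.lmm_fit = fit
        state.varparams = fit.varparams
        eta_new = design.offset + fit.fitted
        state.eta = eta_new
        state.mu = np.clip(np.exp(np.clip(eta_new, np.log(_MU_LO), np.log(_MU_HI))),
                           _MU_LO, _MU_HI)
        theta_old = state.theta
        if update_theta:
            state.theta = update_theta_newton(y, state.mu, state.theta, weights=pw)
        state.n_sweeps += 1
        if beta_prev is not None and len(beta_prev) == len(fit.beta):
            denom = np.maximum(np.abs(beta_prev), 1e-4)
            dbeta = np.max(np.abs(fit.beta - beta_prev) / denom)
            dtheta = abs(np.log(state.theta) - np.log(theta_old))
            if max(dbeta, dtheta) < control.tol:
                state.converged = True
                break
        beta_prev = fit.beta.copy()
    return state


def fit_nbmm(
    response,
    design: DesignBundle,
    control: Optional[FitControl] = None,
    prior_weights=None,
) -> FitResult:
    """Fit the NB mixed model by the PQL/IWLS outer loop.

    Raises on an all-zero response (use the zero-inflated families);
    reaching the iteration cap yields ``converged=False``, not an error.
    """
    control = control or FitControl()
    y = np.asarray(response, dtype=float)
    if np.all(y == 0):
        raise ValueError(
            "response is all zeros; an NB mixed model cannot be fitted "
            "(consider the zero-inflated families)"
        )
    if design.Z is not None and design.n_subjects < 2:
        raise ValueError("mixed-model fitting requires at least 2 subjects")
    warns: list[str] = []
    if np.any(y != np.round(y)):
        warns.append("non-integer counts supplied; proceeding via the "
                     "mean-variance relation")

    mu0, theta0 = _init_mu_theta(y, design.X, design.offset)
    if control.fix_theta is not None:
        theta0 = float(control.fix_theta)
    state = _PQLState(eta=np.log(mu0), mu=mu0, theta=theta0)
    state = _pql_sweeps(y, design, state, control, prior_weights=prior_weights)
    return _result_from_state(y, design, state, control, warns, method="nb")


def _result_from_state(y, design, state: _PQLState, control: FitControl,
                       warns, method) -> FitResult:
    fit = state.lmm_fit
    wt = wald_table(fit, df=control.wald_df)
    if not state.converged:
        warns = warns + ["outer IWLS loop reached the iteration cap"]
    warns = warns + fit.warnings
    vc = None
    if fit.psi.size:
        zn = design.z_names or [f"z{j}" for j in range(fit.psi.shape[0])]
        vc = pd.DataFrame(fit.psi, index=zn, columns=zn)
    return FitResult(
        coef=pd.Series(wt["estimate"].values, index=wt.index),
        se=pd.Series(wt["se"].values, index=wt.index),
        pvalues=pd.Series(wt["pvalue"].values, index=wt.index),
        vc=vc,
        dispersion=state.theta,
        converged=state.converged,
        n_iter=state.n_sweeps,
        method=method,
        warnings=warns,
        loglik=nb_loglik_theta(state.theta, y, state.mu),
        aliased=fit.aliased,
    )
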