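"""Zero-inflated negative binomial mixed models fitted by EM-IWLS.

The observed count is a two-component mixture: a structural zero with
probability p_ij, otherwise an NB(mu_ij, theta) draw, with

    logit(p_ij) = Z_ij alpha            (logistic regression), or
    logit(p_ij) = Z_ij alpha + G_ij a_i (logistic mixed model, a_i ~ N(0, Phi))

and the NB mean modeled as in :mod:`mbmm.nbmm`.  The EM algorithm:

* E-step: posterior probability xi_ij that an observed zero is structural,
  xi = p / (p + (1-p) * P_NB(0 | mu, theta)); xi = 0 at positive counts.
* M-step, zero part: a binomial fit with the fractional responsibilities as
  response (IWLS; PQL loop when the zero part has random effects).
* M-step, count part: capped IWLS sweeps of the NB mixed model with prior
  observation weights (1 - xi) multiplying the working weights.

The responsibilities are probabilities, not 0/1 labels, so the zero-part
binomial is fitted on a fractional response — the standard EM treatment of
mixture membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignBundle, FitResult
from .lmm import LMMProblem, fit_weighted_lmm
from .nbmm import (FitControl, _PQLState, _init_mu_theta, _pql_sweeps,
                   _result_from_state, nb_loglik_theta)

__all__ = [
    "nb_zero_probability",
    "e_step",
    "m_step_zero",
    "fit_zinbmm",
    "ZeroPartState",
]

_P_LO, _P_HI = 1e-6, 1.0 - 1e-6


def nb_zero_probability(mu, theta):
    """P(NB(mu, theta) = 0) = (theta / (theta + mu))^theta, overflow-safe."""
    mu = np.asarray(mu, dtype=float)
    th = np.asarray(theta, dtype=float)
    return np.exp(th * (np.log(th) - np.log(th + mu)))


def e_step(y, p, mu, theta):
    """Posterior structural-zero responsibilities.

    xi = p / (p + (1-p) * P_NB(0|mu,theta)) where y == 0; xi = 0 elsewhere
    (a positive count cannot be a structural zero).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    f0 = nb_zero_probability(mu, theta)
    with np.errstate(invalid="ignore"):
        xi = p / (p + (1.0 - p) * f0)
    xi = np.where(y == 0, xi, 0.0)
    return np.clip(xi, 0.0, 1.0)


@dataclass
class ZeroPartState:
    """Zero-inflation component: coefficients, probabilities, uncertainty."""

    alpha: np.ndarray
    alpha_cov: np.ndarray
    p: np.ndarray                  # fitted zero-inflation probabilities
    phi: Optional[np.ndarray] = None   # zero-part random-effect covariance
    names: Optional[list[str]] = None
    warnings: Optional[list[str]] = None
    varparams: Optional[np.ndarray] = None


def _logistic_iwls(xi, Z, ridge: float = 0.0, maxiter: int = 50, tol: float = 1e-10):
    """Binomial IWLS on a fractional response; returns (alpha, cov, p)."""
    n, p_ = Z.shape
    alpha = np.zeros(p_)
    # intercept warm start at the logit of the mean responsibility
    m = float(np.clip(np.mean(xi), _P_LO, _P_HI))
    icol = np.flatnonzero(np.all(Z == Z[0], axis=0) & (Z[0] != 0))
    if len(icol):
        alpha[icol[0]] = np.log(m / (1 - m)) / Z[0, icol[0]]
    I = np.eye(p_)
    for _ in range(maxiter):
        eta = Z @ alpha
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        mu = np.clip(mu, _P_LO, _P_HI)
        w = mu * (1 - mu)
        z = eta + (xi - mu) / w
        A = Z.T @ (w[:, None] * Z) + ridge * I
        new = np.linalg.solve(A, Z.T @ (w * z))
        if np.max(np.abs(new - alpha)) < tol:
            alpha = new
            break
        alpha = new
    eta = Z @ alpha
    mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), _P_LO, _P_HI)
    w = mu * (1 - mu)
    cov = np.linalg.inv(Z.T @ (w[:, None] * Z) + ridge * np.eye(p_))
    return alpha, cov, mu


def m_step_zero(
    xi_hat,
    Z,
    zi_random: Optional[dict] = None,
    names: Optional[list[str]] = None,
) -> ZeroPartState:
    """M-step for the zero-inflation part.

    Fixed-effects-only: binomial IWLS on the fractional responsibilities.
    With ``zi_random`` (dict with keys ``Z``, ``groups``, ``order``,
    ``correlation``): a PQL loop through the weighted LMM engine.  Perfect
    separation (diverging coefficients) triggers a small ridge penalty
    (1e-4) with a warning; degenerate all-0 / all-1 responsibilities pin
    the probabilities at the clip boundary.
    """
    xi = np.clip(np.asarray(xi_hat, dtype=float), 0.0, 1.0)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    warns: list[str] = []
    if np.all(xi < 1e-12) or np.all(xi > 1 - 1e-12):
        boundary = _P_LO if np.all(xi < 1e-12) else _P_HI
        alpha = np.zeros(Z.shape[1])
        icol = np.flatnonzero(np.all(Z == Z[0], axis=0) & (Z[0] != 0))
        if len(icol):
            alpha[icol[0]] = np.log(boundary / (1 - boundary)) / Z[0, icol[0]]
        warns.append("degenerate responsibilities; zero-part probability at clip boundary")
        return ZeroPartState(alpha=alpha, alpha_cov=np.full((Z.shape[1],) * 2, np.nan),
                             p=np.full(len(xi), boundary), names=names, warnings=warns)

    if zi_random is None:
        alpha, cov, p = _logistic_iwls(xi, Z)
        if not np.all(np.isfinite(alpha)) or np.max(np.abs(alpha)) > 25:
            warns.append("separation in zero-part logistic fit; ridge fallback")
            alpha, cov, p = _logistic_iwls(xi, Z, ridge=1e-4)
        return ZeroPartState(alpha=alpha, alpha_cov=cov, p=np.clip(p, _P_LO, _P_HI),
                             names=names, warnings=warns)

    # logistic mixed model via PQL on the LMM engine
    Gr = zi_random
    alpha = np.zeros(Z.shape[1])
    eta = np.full(len(xi), np.log(np.clip(xi.mean(), _P_LO, _P_HI)
                                  / (1 - np.clip(xi.mean(), _P_LO, _P_HI))))
    varparams = Gr.get("varparams")
    fit = None
    for _ in range(15):
        mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), _P_LO, _P_HI)
        w = mu * (1 - mu)
        z = eta + (xi - mu) / w
        prob = LMMProblem(
            y=z, X=Z, groups=Gr["groups"], Z=Gr["Z"], weights=w,
            correlation=Gr.get("correlation", "none"), order=Gr.get("order"),
            x_names=names,
        )
        fit = fit_weighted_lmm(prob, method="ML", start=varparams)
        varparams = fit.varparams
        eta_new = fit.fitted
        if np.max(np.abs(eta_new - eta)) < 1e-6:
            eta = eta_new
            break
        eta = eta_new
    p_fit = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30))), _P_LO, _P_HI)
    return ZeroPartState(alpha=fit.beta, alpha_cov=fit.beta_cov, p=p_fit,
                         phi=fit.psi, names=fit.x_names, warnings=fit.warnings,
                         varparams=varparams)


def zinb_loglik(y, p, mu, theta) -> float:
    """Observed-data ZINB log-likelihood (fixed parameters)."""
    y = np.asarray(y, dtype=float)
    f0 = nb_zero_probability(mu, theta)
    from scipy import special

    nb_ll = (special.gammaln(y + theta) - special.gammaln(theta)
             - special.gammaln(y + 1.0) + theta * np.log(theta)
             + y * np.log(np.clip(mu, 1e-300, None))
             - (y + theta) * np.log(theta + mu))
    zero_term = np.log(np.clip(p + (1 - p) * f0, 1e-300, None))
    pos_term = np.log(np.clip(1 - p, 1e-300, None)) + nb_ll
    return float(np.sum(np.where(y == 0, zero_term, pos_term)))


def fit_zinbmm(
    response,
    design: DesignBundle,
    control: Optional[FitControl] = None,
    force_p_zero: bool = False,
) -> FitResult:
    """Fit the ZINB mixed model by EM-IWLS.

    ``force_p_zero=True`` pins the structural-zero probability at 0, which
    reduces the model exactly to the NB mixed model; the fit is then
    delegated to :func:`mbmm.nbmm.fit_nbmm` so the two paths coincide.
    """
    control = control or FitControl()
    y = np.asarray(response, dtype=float)
    if np.all(y == 0):
        raise ValueError("response is all zeros; the mixture is not identifiable")
    from .nbmm import fit_nbmm

    if force_p_zero:
        return fit_nbmm(y, design, control)
    if not np.any(y == 0):
        warnings.warn("response has no zeros; falling back to the NB mixed model")
        res = fit_nbmm(y, design, control)
        res.warnings = res.warnings + ["no zeros observed: fitted as plain NBMM"]
        return res

    Zzi = design.zi_X if design.zi_X is not None else np.ones((len(y), 1))
    zi_names = design.zi_names or ["Intercept"]
    zi_random = None
    if design.zi_Z is not None:
        zi_random = {"Z": design.zi_Z, "groups": design.groups,
                     "order": design.order, "correlation": "none"}

    # init: constant p at the empirical zero fraction; NB part from Poisson GLM
    p0 = float(np.clip(np.mean(y == 0), 0.01, 0.95))
    p = np.full(len(y), p0)
    mu0, theta0 = _init_mu_theta(y, design.X, design.offset)
    state = _PQLState(eta=np.log(mu0), mu=mu0, theta=theta0)
    xi = e_step(y, p, state.mu, state.theta)
    state = _pql_sweeps(y, design, state, control,
                        prior_weights=np.clip(1 - xi, 1e-8, None),
                        max_sweeps=control.inner_sweeps)

    zero_state = None
    prev = None
    converged = False
    n_em = 0
    for n_em in range(1, control.max_em + 1):
        xi = e_step(y, p, state.mu, state.theta)
        zero_state = m_step_zero(xi, Zzi, zi_random=zi_random, names=zi_names)
        if zi_random is not None:
            zi_random["varparams"] = zero_state.varparams
        p = zero_state.p
        state.converged = False
        state = _pql_sweeps(y, design, state, control,
                            prior_weights=np.clip(1 - xi, 1e-8, None),
                            max_sweeps=control.inner_sweeps)
        params = np.concatenate([state.lmm_fit.beta, zero_state.alpha,
                                 [np.log(state.theta)]])
        if prev is not None and len(prev) == len(params):
            if np.max(np.abs(params - prev)) < control.em_tol:
                converged = True
                break
        prev = params

    state.converged = converged
    res = _result_from_state(y, design, state, control,
                             warns=list(zero_state.warnings or []), method="zinb")
    res.n_iter = n_em
    se_a = np.sqrt(np.clip(np.diag(zero_state.alpha_cov), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = np.where(se_a > 0, zero_state.alpha / se_a, np.inf)
        pv = np.where(np.isfinite(se_a) & (se_a > 0),
                      2 * stats.norm.sf(np.abs(zstat)), np.nan)
    res.zero_coef = pd.Series(zero_state.alpha, index=zi_names)
    res.zero_se = pd.Series(np.where(np.isfinite(se_a), se_a, 0.0), index=zi_names)
    res.zero_pvalues = pd.Series(np.clip(np.nan_to_num(pv, nan=1.0), 0, 1),
                                 index=zi_names)
    if zero_state.phi is not None and zero_state.phi.size:
        zn = design.zi_z_names or [f"z{j}" for j in range(zero_state.phi.shape[0])]
        res.zero_vc = pd.DataFrame(zero_state.phi, index=zn, columns=zn)
    res.loglik = zinb_loglik(y, p, state.mu, state.theta)
    return res
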