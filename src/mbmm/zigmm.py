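"""Zero-inflated Gaussian mixed models on transformed abundances.

Counts are transformed as y = log2(C + 1) and proportions as
y = arcsin(sqrt(C/T)); both map a raw zero to an exact zero, so the
zero-inflation component keys on exact zeros of the transformed response.
The model is

    y_ij = 0                      with probability p_ij
    y_ij ~ N(mu_ij, sigma^2)      with probability 1 - p_ij

with mu_ij = offset_ij + X_ij beta + Z_ij b_i, b_i ~ N(0, Psi), and a
logistic (optionally mixed) model for p_ij as in :mod:`mbmm.zinbmm`.

EM structure:

* E-step: at exact zeros, xi = p / (p + (1-p) * phi(0; mu, sigma^2)) with
  phi the Gaussian density; xi = 0 at nonzero responses.
* M-step: the shared zero-part fit of :func:`mbmm.zinbmm.m_step_zero`, and
  a weighted LMM for the Gaussian branch with prior weights (1 - xi).  The
  residual variance is updated as sum((1-xi) r^2) / sum(1-xi), the
  EM-consistent divisor.

For count inputs whose offset policy requests a library-size offset, the
ln-scale totals are divided by ln 2 so the offset lives on the log2
response scale.  Offsets are rejected for proportion responses.

An input with no exact zeros short-circuits: xi is identically 0 and the
result is exactly the plain weighted-LMM fit.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .data import DesignBundle, FitResult
from .lmm import LMMProblem, fit_weighted_lmm, wald_table
from .nbmm import FitControl
from .zinbmm import ZeroPartState, m_step_zero

__all__ = ["zig_e_step", "fit_zigmm", "zig_loglik"]

_P_LO, _P_HI = 1e-6, 1.0 - 1e-6


def zig_e_step(y, p, mu, sigma2):
    """Posterior structural-zero responsibilities for the Gaussian mixture.

    xi = p / (p + (1-p) * phi(0; mu, sigma2)) exactly at y == 0, else 0.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(np.asarray(sigma2) <= 0):
        raise ValueError("sigma2 must be positive")
    dens0 = np.exp(-0.5 * mu ** 2 / sigma2) / np.sqrt(2 * np.pi * sigma2)
    with np.errstate(invalid="ignore"):
        xi = p / (p + (1.0 - p) * dens0)
    return np.clip(np.where(y == 0, xi, 0.0), 0.0, 1.0)


def zig_loglik(y, p, mu, sigma2) -> float:
    """Observed-data log-likelihood at fixed parameters (exact for
    fixed-effects-only fits, where mu carries no random effects)."""
    y = np.asarray(y, dtype=float)
    dens = np.exp(-0.5 * (y - mu) ** 2 / sigma2) / np.sqrt(2 * np.pi * sigma2)
    zero_term = np.log(np.clip(p + (1 - p) * dens, 1e-300, None))
    pos_term = np.log(np.clip((1 - p) * dens, 1e-300, None))
    return float(np.sum(np.where(y == 0, zero_term, pos_term)))


def _gaussian_mstep(y, design: DesignBundle, xi, control: FitControl, varparams):
    w = np.clip(1.0 - xi, 1e-8, None)
    prob = LMMProblem(
        y=y, X=design.X, groups=design.groups, Z=design.Z, weights=w,
        offset=design.offset, correlation=design.correlation,
        order=design.order, x_names=design.x_names, z_names=design.z_names,
    )
    fit = fit_weighted_lmm(prob, method=control.lmm_method, start=varparams)
    resid = y - fit.fitted
    sigma2 = float(np.sum((1.0 - xi) * resid ** 2) / max(np.sum(1.0 - xi), 1e-12))
    return fit, max(sigma2, 1e-12), w


def fit_zigmm(
    response,
    design: DesignBundle,
    control: Optional[FitControl] = None,
) -> FitResult:
    """Fit the zero-inflated Gaussian mixed model by EM."""
    control = control or FitControl()
    y = np.asarray(response, dtype=float)
    if np.all(y == 0):
        raise ValueError("response is all zeros; the mixture is not identifiable")

    has_zeros = bool(np.any(y == 0))
    Zzi = design.zi_X if design.zi_X is not None else np.ones((len(y), 1))
    zi_names = design.zi_names or ["Intercept"]
    zi_random = None
    if design.zi_Z is not None:
        zi_random = {"Z": design.zi_Z, "groups": design.groups,
                     "order": design.order, "correlation": "none"}

    if not has_zeros:
        # degenerate reduction: xi == 0 everywhere, single unit-weight LMM fit
        xi = np.zeros(len(y))
        fit, sigma2, _ = _gaussian_mstep(y, design, xi, control, None)
        res = _zig_result(y, design, fit, sigma2, control,
                          zero_state=None, zi_names=zi_names, n_iter=1,
                          converged=True, trace=None)
        res.warnings.append("no exact zeros: zero-inflation component inactive")
        return res

    fixed_only = design.Z is None and design.correlation == "none"

    p0 = float(np.clip(np.mean(y == 0), 0.01, 0.95))
    p = np.full(len(y), p0)
    xi = np.where(y == 0, p0, 0.0)
    fit, sigma2, _ = _gaussian_mstep(y, design, xi, control, None)
    varparams = fit.varparams

    zero_state: Optional[ZeroPartState] = None
    prev = None
    converged = False
    trace: list[float] = []
    n_em = 0
    for n_em in range(1, control.max_em + 1):
        xi = zig_e_step(y, p, fit.fitted, sigma2)
        zero_state = m_step_zero(xi, Zzi, zi_random=zi_random, names=zi_names)
        if zi_random is not None:
            zi_random["varparams"] = zero_state.varparams
        p = zero_state.p
        fit, sigma2, _ = _gaussian_mstep(y, design, xi, control, varparams)
        varparams = fit.varparams
        if fixed_only:
            trace.append(zig_loglik(y, p, fit.fitted, sigma2))
        # convergence on the probability scale: a zero-part logit sliding to
        # a boundary (p -> 0 or 1) then counts as converged at the boundary
        params = np.concatenate([fit.beta, p, [np.log(sigma2)]])
        if prev is not None and len(prev) == len(params):
            if np.max(np.abs(params - prev)) < control.em_tol:
                converged = True
                break
        prev = params
    if not converged:
        warnings.warn("ZIG EM reached the iteration cap without meeting tolerance")

    return _zig_result(y, design, fit, sigma2, control, zero_state, zi_names,
                       n_iter=n_em, converged=converged,
                       trace=trace if fixed_only else None)


def _zig_result(y, design, fit, sigma2, control, zero_state, zi_names,
                n_iter, converged, trace) -> FitResult:
    from scipy import stats

    wt = wald_table(fit, df=control.wald_df)
    vc = None
    if fit.psi.size:
        zn = design.z_names or [f"z{j}" for j in range(fit.psi.shape[0])]
        vc = pd.DataFrame(fit.psi, index=zn, columns=zn)
    res = FitResult(
        coef=pd.Series(wt["estimate"].values, index=wt.index),
        se=pd.Series(wt["se"].values, index=wt.index),
        pvalues=pd.Series(wt["pvalue"].values, index=wt.index),
        vc=vc,
        dispersion=sigma2,
        converged=converged,
        n_iter=n_iter,
        method="zig",
        warnings=list(fit.warnings),
        loglik=fit.loglik,
        loglik_trace=trace,
        aliased=fit.aliased,
    )
    if zero_state is not None:
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
        res.loglik = zig_loglik(y, zero_state.p, fit.fitted, sigma2)
        res.warnings.extend(zero_state.warnings or [])
    return res
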