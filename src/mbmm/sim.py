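"""Synthetic multilevel longitudinal microbiome-like data with known truth.

The generator emulates the structure of a longitudinal 16S/shotgun study:
subjects carry a binary group label (case/control), samples within subject
are ordered in time, per-sample library sizes vary over an order of
magnitude, counts are NB over-dispersed around a log-linear mean with a
subject-level random intercept (optionally slope), and structural zeros
arrive through a logistic model on covariates.  Panels may be unbalanced:
the number of samples per subject is drawn uniformly from a range.

Default covariate design: a subject-level binary ``group``, a sample-level
``time`` on [0, 1], and a subject-level continuous nuisance ``age``
(standardized).  The fixed-effect vector ``beta`` matches columns
``[Intercept, group, time, age]`` truncated to its length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import SampleMeta, TaxaTable

__all__ = ["SimTruth", "SimulatedDataset", "simulate_nbmm", "simulate_zinbmm",
           "simulate_zigmm"]


@dataclass
class SimTruth:
    """Generating parameters of one synthetic dataset.

    ``psi`` is the random-effect covariance: a scalar is a random-intercept
    variance, a matrix covers intercept + slope.  The zero part is either a
    constant probability ``p_zero`` or a logistic law with coefficients
    ``alpha`` over [Intercept, group].
    """

    n_subjects: int = 100
    samples_per_subject: tuple[int, int] = (5, 5)
    beta: Sequence[float] = (1.0, 0.5)
    theta: float = 2.0
    psi: float | Sequence = 0.25          # random-intercept variance (SD 0.5)
    alpha: Optional[Sequence[float]] = None
    p_zero: Optional[float] = None
    sigma: float = 0.6                    # Gaussian residual SD (ZIG)
    rho: float = 0.0                      # AR(1) residual correlation (ZIG)
    total_reads_range: tuple[float, float] = (5e3, 5e4)
    n_taxa: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if np.any(np.linalg.eigvalsh((psi + psi.T) / 2) < -1e-12):
            raise ValueError("psi must be positive semi-definite")
        if self.theta <= 0 or self.sigma < 0:
            raise ValueError("variance parameters must be non-negative")

    @property
    def psi_matrix(self) -> np.ndarray:
        return np.atleast_2d(np.asarray(self.psi, dtype=float))


@dataclass
class SimulatedDataset:
    """A generated dataset plus the truth that produced it.

    ``table`` is a :class:`TaxaTable` for the count generators and a plain
    DataFrame (samples x taxa, transformed scale) for the Gaussian one.
    """

    table: "TaxaTable | pd.DataFrame"
    meta: SampleMeta
    truth: SimTruth
    latent_zero: Optional[np.ndarray] = None   # structural-zero indicators
    mu: Optional[np.ndarray] = None            # conditional means (first taxon)

    def __iter__(self):
        # allow (table, meta, truth) unpacking
        return iter((self.table, self.meta, self.truth))


def _layout(truth: SimTruth, rng: np.random.Generator):
    lo, hi = truth.samples_per_subject
    n_i = rng.integers(lo, hi + 1, size=truth.n_subjects)
    subj = np.repeat(np.arange(truth.n_subjects), n_i)
    order = np.concatenate([np.arange(k) for k in n_i])
    time = np.concatenate([np.linspace(0.0, 1.0, k) if k > 1 else np.zeros(1)
                           for k in n_i])
    group = rng.binomial(1, 0.5, size=truth.n_subjects)
    age = rng.normal(size=truth.n_subjects)
    meta = pd.DataFrame(
        {
            "subject": [f"S{j:03d}" for j in subj],
            "time": time,
            "group": group[subj],
            "age": age[subj],
            "total_reads": rng.uniform(*truth.total_reads_range, size=len(subj)),
        },
        index=[f"S{j:03d}_t{k}" for j, k in zip(subj, order)],
    )
    X = np.column_stack([np.ones(len(subj)), group[subj], time, age[subj]])
    return meta, X, subj


def _linear_predictor(truth, X, subj, rng, with_offset, meta):
    beta = np.asarray(truth.beta, dtype=float)
    psi = truth.psi_matrix
    q = psi.shape[0]
    b = rng.multivariate_normal(np.zeros(q), psi, size=truth.n_subjects) if q else None
    Zr = np.column_stack([np.ones(len(subj)), meta["time"].values])[:, :q]
    eta = X[:, : len(beta)] @ beta
    if q:
        eta = eta + np.einsum("nq,nq->n", Zr, b[subj])
    if with_offset:
        eta = eta + np.log(meta["total_reads"].values)
    return eta


def _zero_probs(truth: SimTruth, X) -> Optional[np.ndarray]:
    if truth.p_zero is not None:
        return np.full(X.shape[0], float(truth.p_zero))
    if truth.alpha is not None:
        a = np.asarray(truth.alpha, dtype=float)
        Z = X[:, : len(a)]  # [Intercept, group, ...]
        return 1.0 / (1.0 + np.exp(-(Z @ a)))
    return None


def _make_table(counts2d, meta, truth, is_proportion=False) -> TaxaTable:
    return TaxaTable(
        counts=counts2d,
        taxon_ids=[f"taxon_{h + 1}" for h in range(counts2d.shape[1])],
        sample_ids=list(meta.index),
        is_proportion=is_proportion,
    )


def simulate_nbmm(truth: SimTruth) -> SimulatedDataset:
    """Draw NB counts: C ~ NB(mu, theta) with
    log mu = log T + X beta + Z b, b ~ N(0, Psi).  Fully reproducible from
    ``truth.seed`` (the NB draw uses the gamma-Poisson mixture)."""
    rng = np.random.default_rng(truth.seed)
    meta, X, subj = _layout(truth, rng)
    cols = []
    mu0 = None
    for h in range(truth.n_taxa):
        eta = _linear_predictor(truth, X, subj, rng, with_offset=True, meta=meta)
        mu = np.exp(eta)
        if h == 0:
            mu0 = mu
        lam = rng.gamma(truth.theta, mu / truth.theta)
        cols.append(rng.poisson(lam).astype(float))
    table = _make_table(np.column_stack(cols), meta, truth)
    return SimulatedDataset(table=table, meta=SampleMeta(meta), truth=replace(truth),
                            mu=mu0)


def simulate_zinbmm(truth: SimTruth) -> SimulatedDataset:
    """As :func:`simulate_nbmm`, then zero out each cell independently with
    probability p_ij (constant or logistic in [Intercept, group]).  The
    latent structural-zero indicators of the first taxon are recorded."""
    rng = np.random.default_rng(truth.seed)
    meta, X, subj = _layout(truth, rng)
    p = _zero_probs(truth, X)
    cols, latent0, mu0 = [], None, None
    for h in range(truth.n_taxa):
        eta = _linear_predictor(truth, X, subj, rng, with_offset=True, meta=meta)
        mu = np.exp(eta)
        lam = rng.gamma(truth.theta, mu / truth.theta)
        y = rng.poisson(lam).astype(float)
        if p is not None:
            latent = rng.binomial(1, p).astype(bool)
            y = np.where(latent, 0.0, y)
        else:
            latent = np.zeros(len(y), dtype=bool)
        if h == 0:
            latent0, mu0 = latent, mu
        cols.append(y)
    table = _make_table(np.column_stack(cols), meta, truth)
    return SimulatedDataset(table=table, meta=SampleMeta(meta), truth=replace(truth),
                            latent_zero=latent0, mu=mu0)


def simulate_zigmm(truth: SimTruth) -> SimulatedDataset:
    """Zero-inflated Gaussian responses on the transformed scale: y = 0 with
    probability p, else N(mu, sigma^2) with mu = X beta + Z b (no offset).
    Within-subject residuals may be AR(1)-correlated via ``truth.rho``."""
    rng = np.random.default_rng(truth.seed)
    meta, X, subj = _layout(truth, rng)
    p = _zero_probs(truth, X)
    cols, latent0, mu0 = [], None, None
    order = meta.groupby("subject", sort=False).cumcount().values
    for h in range(truth.n_taxa):
        eta = _linear_predictor(truth, X, subj, rng, with_offset=False, meta=meta)
        eps = rng.normal(size=len(eta))
        if truth.rho != 0.0:
            # AR(1) innovation filter within subject
            for s in np.unique(subj):
                idx = np.flatnonzero(subj == s)
                for k in range(1, len(idx)):
                    eps[idx[k]] = (truth.rho * eps[idx[k - 1]]
                                   + np.sqrt(1 - truth.rho ** 2) * eps[idx[k]])
        y = eta + truth.sigma * eps
        if p is not None:
            latent = rng.binomial(1, p).astype(bool)
            y = np.where(latent, 0.0, y)
        else:
            latent = np.zeros(len(y), dtype=bool)
        if h == 0:
            latent0, mu0 = latent, eta
        cols.append(y)
    # transformed-scale responses may be negative, so a plain frame (not a
    # TaxaTable, whose entries are non-negative abundances) carries them
    df = pd.DataFrame(np.column_stack(cols),
                      columns=[f"taxon_{h + 1}" for h in range(truth.n_taxa)],
                      index=meta.index)
    return SimulatedDataset(table=df, meta=SampleMeta(meta), truth=replace(truth),
                            latent_zero=latent0, mu=mu0)
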