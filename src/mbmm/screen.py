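"""Many-taxa screening: filter, fit every retained taxon, collect results.

This is the workhorse for whole-table analyses: taxa whose nonzero
proportion does not exceed ``min_p`` are skipped, every retained taxon is
fitted independently with the requested model family, and a failure in one
taxon is recorded without aborting the run or perturbing any other taxon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import (DesignBundle, FitResult, ModelSpec, SampleMeta, TaxaTable,
                   arcsine_sqrt_transform, build_design, log2_transform,
                   nonzero_proportions)
from .nbmm import FitControl, fit_nbmm
from .lmm import LMMProblem, fit_weighted_lmm, wald_table
from .zigmm import fit_zigmm
from .zinbmm import fit_zinbmm

__all__ = ["ScreenResult", "screen", "fixed_table", "get_fixed", "adjust_pvalues"]

_LN2 = float(np.log(2.0))


@dataclass
class ScreenResult:
    """Ordered per-taxon fits plus filter/failure bookkeeping.

    ``fits`` and ``skipped`` together cover every input taxon exactly once;
    ``order`` is the analysis order actually used.
    """

    fits: dict[str, FitResult] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)
    spec: Optional[ModelSpec] = None
    min_p: float = 0.0
    sort: bool = False

    @property
    def n_fitted(self) -> int:
        return len(self.fits)


def _response_for(method, raw, totals, is_proportion, transform):
    """Pick the response actually modeled for one taxon."""
    if method in ("nb", "zinb"):
        return raw
    if method in ("zig", "lmm"):
        tr = transform or ("asinsqrt" if is_proportion else "log2count")
        if tr == "log2count":
            return log2_transform(raw)
        if tr == "asinsqrt":
            if totals is None:
                raise ValueError("arcsine-sqrt transform needs total reads")
            return arcsine_sqrt_transform(raw, totals)
        if tr == "none":
            return np.asarray(raw, dtype=float)
        raise ValueError(f"unknown transform {tr!r}")
    raise ValueError(f"unknown method {method!r}")


def _fit_one(y, design: DesignBundle, spec: ModelSpec, control: FitControl) -> FitResult:
    if spec.method == "nb":
        return fit_nbmm(y, design, control)
    if spec.method == "zinb":
        return fit_zinbmm(y, design, control)
    if spec.method == "zig":
        return fit_zigmm(y, design, control)
    # plain LMM on the transformed response
    prob = LMMProblem(
        y=np.asarray(y, float), X=design.X, groups=design.groups, Z=design.Z,
        offset=design.offset, correlation=design.correlation, order=design.order,
        x_names=design.x_names, z_names=design.z_names,
    )
    fit = fit_weighted_lmm(prob, method=control.lmm_method)
    wt = wald_table(fit, df=control.wald_df)
    vc = None
    if fit.psi.size:
        zn = design.z_names or [f"z{j}" for j in range(fit.psi.shape[0])]
        vc = pd.DataFrame(fit.psi, index=zn, columns=zn)
    return FitResult(
        coef=pd.Series(wt["estimate"].values, index=wt.index),
        se=pd.Series(wt["se"].values, index=wt.index),
        pvalues=pd.Series(wt["pvalue"].values, index=wt.index),
        vc=vc, dispersion=fit.sigma2, converged=fit.converged,
        n_iter=fit.n_iter, method="lmm", warnings=list(fit.warnings),
        loglik=fit.loglik, aliased=fit.aliased,
    )


def screen(
    table: TaxaTable,
    meta: SampleMeta,
    spec: ModelSpec,
    min_p: float = 0.0,
    sort: bool = False,
    control: Optional[FitControl] = None,
) -> ScreenResult:
    """Fit the chosen model family to every taxon whose nonzero proportion
    exceeds ``min_p`` (strict inequality).

    When ``sort`` is true, taxa are analyzed in decreasing order of nonzero
    proportion (ties broken by input order).  Per-taxon exceptions are
    caught and recorded as ``failed``; nothing aborts the run.
    """
    if list(table.sample_ids) != list(meta.sample_ids):
        raise ValueError("taxa table and metadata sample ids are not aligned")
    control = control or FitControl()
    props = nonzero_proportions(table)

    taxa = list(table.taxon_ids)
    if sort:
        taxa = sorted(taxa, key=lambda t: (-props[t], table.taxon_ids.index(t)))

    result = ScreenResult(spec=spec, min_p=min_p, sort=sort)
    totals = meta.total_reads
    fitted_any = False
    for t in taxa:
        result.order.append(t)
        if not (props[t] > min_p):
            result.skipped[t] = "filtered"
            continue
        try:
            raw = table.taxon(t)
            y = _response_for(spec.method, raw, totals, table.is_proportion,
                              spec.transform)
            if table.is_proportion and spec.offset_policy != "none":
                raise ValueError("offset must be 'none' for proportion responses")
            design = build_design(meta, spec, y)
            y_used = design.y
            if spec.method == "zig" and (spec.transform or "log2count") == "log2count" \
                    and not table.is_proportion and spec.offset_policy == "log_total_reads":
                design.offset = design.offset / _LN2  # log2-scale library size
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result.fits[t] = _fit_one(y_used, design, spec, control)
            fitted_any = True
        except Exception as err:  # fault isolation: record, continue
            result.skipped[t] = f"failed: {err}"
    if not fitted_any:
        warnings.warn("no taxa were fitted (all filtered or failed)")
    return result


def fixed_table(result: ScreenResult) -> pd.DataFrame:
    """Long results table: one row per (taxon, coefficient, part).

    Rows follow the analysis order, with count-part coefficients before
    zero-part ones inside each taxon; failed taxa contribute no rows.
    """
    frames = []
    for t in result.order:
        if t not in result.fits:
            continue
        f = result.fits[t].to_frame()
        f.insert(0, "taxon", t)
        f["converged"] = result.fits[t].converged
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["taxon", "term", "part", "estimate", "se",
                                     "pvalue", "converged"])
    return pd.concat(frames, ignore_index=True)


def get_fixed(result: ScreenResult, vr_name: str, part: str = "count") -> pd.DataFrame:
    """Per-taxon slice of one coefficient across all fitted taxa.

    Taxa in which the term was aliased out are omitted (noted in the
    ``note`` attribute of the returned frame).
    """
    table = fixed_table(result)
    if table.empty:
        raise ValueError("screen produced no fitted taxa")
    avail = sorted(table.loc[table["part"] == part, "term"].unique())
    if vr_name not in avail:
        raise KeyError(
            f"term {vr_name!r} not found; available terms: {', '.join(avail)}"
        )
    out = table[(table["term"] == vr_name) & (table["part"] == part)].copy()
    out = out.set_index("taxon")[["estimate", "se", "pvalue"]]
    missing = [t for t in result.fits if t not in out.index]
    out.attrs["note"] = (
        f"term aliased out in: {', '.join(missing)}" if missing else ""
    )
    return out


def adjust_pvalues(table: pd.DataFrame, method: str = "BH") -> pd.DataFrame:
    """Add an ``adjusted`` column; BH step-up within each (term, part)
    across taxa, or a plain copy for ``method='none'``."""
    out = table.copy()
    if method == "none":
        out["adjusted"] = out["pvalue"]
        return out
    if method != "BH":
        raise ValueError(f"unknown adjustment method {method!r}")
    out["adjusted"] = np.nan
    for _, idx in out.groupby(["term", "part"]).groups.items():
        pv = out.loc[idx, "pvalue"].values
        ok = np.isfinite(pv)
        adj = np.full(len(pv), np.nan)
        if ok.any():
            adj[ok] = multipletests(pv[ok], method="fdr_bh")[1]
        out.loc[idx, "adjusted"] = adj
    return out
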