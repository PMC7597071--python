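"""Graphical summaries of screening results.

Both plots return the exact numeric objects rendered (a table for the
forest plot, a matrix plus sign mask for the heat map) so tests can check
the numbers without image comparison; rendering is side-effect only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PlotSpec", "plot_fixed", "heat_p"]

_Z95 = 1.96  # normal 95% interval multiplier


@dataclass
class PlotSpec:
    """Display controls for the result plots."""

    alpha: float = 0.05
    terms: Optional[Sequence[str]] = None
    significant_only: bool = False
    abbreviate_taxa: bool = True
    max_label: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def _abbreviate(labels: Sequence[str], limit: int) -> list[str]:
    """Truncate labels to ``limit`` characters, suffixing duplicates."""
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        short = lab[:limit]
        if short in seen:
            seen[short] += 1
            short = f"{short[: limit - 2]}~{seen[short]}"
        else:
            seen[short] = 0
        out.append(short)
    return out


def _filter_table(table: pd.DataFrame, spec: PlotSpec) -> pd.DataFrame:
    tab = table[table["part"] == "count"] if "part" in table.columns else table
    tab = tab[tab["term"] != "Intercept"]
    if spec.terms is not None:
        tab = tab[tab["term"].isin(list(spec.terms))]
    if spec.significant_only:
        tab = tab[tab["pvalue"] < spec.alpha]
    return tab.copy()


def plot_fixed(table: pd.DataFrame, spec: Optional[PlotSpec] = None,
               out=None, ax=None) -> pd.DataFrame:
    """Forest-style plot of fixed effects with 95% intervals and p-values.

    One row per (taxon, term): point estimate, interval estimate +- 1.96*se,
    significant (p < alpha) and insignificant effects in distinct colors,
    p-values annotated in the right margin.  Returns the plotted table.
    """
    spec = spec or PlotSpec()
    tab = _filter_table(table, spec)
    if tab.empty:
        warnings.warn("nothing to plot: no rows satisfy the display filter")
        return tab.assign(lo=[], hi=[], significant=[])
    tab["lo"] = tab["estimate"] - _Z95 * tab["se"]
    tab["hi"] = tab["estimate"] + _Z95 * tab["se"]
    tab["significant"] = tab["pvalue"] < spec.alpha

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(figsize=(7, max(2.5, 0.28 * len(tab))))
    labels = [f"{t}: {m}" for t, m in zip(tab["taxon"], tab["term"])]
    if spec.abbreviate_taxa:
        labels = _abbreviate(labels, spec.max_label + 12)
    ypos = np.arange(len(tab))[::-1]
    for sig, color in ((True, "tab:red"), (False, "tab:gray")):
        m = tab["significant"].values == sig
        ax.errorbar(tab["estimate"].values[m], ypos[m],
                    xerr=_Z95 * tab["se"].values[m],
                    fmt="o", color=color, ecolor=color, capsize=2,
                    label="significant" if sig else "insignificant")
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=7)
    for y, p in zip(ypos, tab["pvalue"]):
        ax.annotate(f"{p:.3g}", xy=(1.01, y), xycoords=("axes fraction", "data"),
                    fontsize=6, va="center")
    ax.set_xlabel("estimate (95% interval)")
    ax.legend(fontsize=7, loc="best")
    if created:
        fig.tight_layout()
        if out is not None:
            fig.savefig(out, dpi=150)
        plt.close(fig)
    return tab


def heat_p(table: pd.DataFrame, spec: Optional[PlotSpec] = None,
           out=None, ax=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Taxa-by-terms heat map of p-values with "+" marking significant
    positive effects.

    Returns ``(pmatrix, signmask)``; the mask is True only where the effect
    is significant AND positive.  Combinations absent from the table (e.g.
    aliased terms) stay missing (NaN), never zero.
    """
    spec = spec or PlotSpec()
    tab = _filter_table(table, PlotSpec(alpha=spec.alpha, terms=spec.terms))
    if tab.empty:
        raise ValueError("heat map needs at least one taxon x term cell")
    pmat = tab.pivot_table(index="taxon", columns="term", values="pvalue",
                           aggfunc="first", sort=False)
    emat = tab.pivot_table(index="taxon", columns="term", values="estimate",
                           aggfunc="first", sort=False)
    sign_mask = (pmat < spec.alpha) & (emat > 0)
    sign_mask = sign_mask.where(pmat.notna(), other=False)

    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = ax is None
    if created:
        fig, ax = plt.subplots(
            figsize=(1.2 + 0.6 * pmat.shape[1], max(2.0, 0.3 * pmat.shape[0]))
        )
    with np.errstate(divide="ignore"):
        score = np.minimum(-np.log10(pmat.values.astype(float)), 10.0)
    im = ax.imshow(np.ma.masked_invalid(score), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=10.0)
    ax.set_xticks(range(pmat.shape[1]))
    ax.set_xticklabels(pmat.columns, rotation=45, ha="right", fontsize=7)
    labels = list(pmat.index)
    if spec.abbreviate_taxa:
        labels = _abbreviate(labels, spec.max_label)
    ax.set_yticks(range(pmat.shape[0]))
    ax.set_yticklabels(labels, fontsize=7)
    for i in range(pmat.shape[0]):
        for j in range(pmat.shape[1]):
            if bool(sign_mask.values[i, j]):
                ax.text(j, i, "+", ha="center", va="center",
                        color="white", fontsize=9, fontweight="bold")
    if created:
        fig.colorbar(im, ax=ax, label="-log10 p (capped at 10)")
        fig.tight_layout()
        if out is not None:
            fig.savefig(out, dpi=150)
        plt.close(fig)
    return pmat, sign_mask
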