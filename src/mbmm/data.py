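"""Data containers, transformations and file I/O shared by all model fitters.

The package operates on two aligned tables: a samples-by-taxa abundance
matrix (:class:`TaxaTable`) and a per-sample metadata table
(:class:`SampleMeta`) carrying the subject grouping, optional time variable,
total sequencing reads and any covariates.  A :class:`ModelSpec` bundles the
formulas and fitting options, and :func:`build_design` turns the three into
the numeric design bundle consumed by the fitters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy

__all__ = [
    "TaxaTable",
    "SampleMeta",
    "ModelSpec",
    "FitResult",
    "DesignBundle",
    "read_taxa_table",
    "read_sample_meta",
    "log2_transform",
    "arcsine_sqrt_transform",
    "nonzero_proportions",
    "build_design",
    "write_results_table",
    "read_results_table",
]


class SpecificationError(ValueError):
    """A model specification references data that is absent or inconsistent."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (duplicates, negatives)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TaxaTable:
    """Abundance matrix for m taxa across samples, oriented samples x taxa.

    ``counts`` may hold raw sequence counts or (scaled) relative abundances;
    ``is_proportion`` records which, because it decides the transformation
    and offset policy downstream.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    is_proportion: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise IntegrityError("counts must be a 2-d samples x taxa matrix")
        n, m = self.counts.shape
        if n != len(self.sample_ids) or m != len(self.taxon_ids):
            raise IntegrityError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.taxon_ids)) != m:
            raise IntegrityError("taxon_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise IntegrityError("sample_ids are not unique")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise IntegrityError("counts contain negative or non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def taxon(self, taxon_id: str) -> np.ndarray:
        """Abundance vector of one taxon across samples."""
        return self.counts[:, self.taxon_ids.index(taxon_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class SampleMeta:
    """Per-sample metadata: subject grouping, time, library size, covariates.

    ``data`` is indexed by sample id.  The subject column maps every sample
    to exactly one subject; subjects may contribute unequal numbers of
    samples (unbalanced longitudinal designs are fully supported).
    """

    data: pd.DataFrame
    subject_col: str = "subject"
    time_col: Optional[str] = "time"
    total_reads_col: Optional[str] = "total_reads"

    def __post_init__(self) -> None:
        if self.subject_col not in self.data.columns:
            raise SpecificationError(f"subject column {self.subject_col!r} not in metadata")
        if self.time_col is not None and self.time_col not in self.data.columns:
            self.time_col = None
        if self.total_reads_col is not None and self.total_reads_col not in self.data.columns:
            self.total_reads_col = None
        if self.data.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def subjects(self) -> pd.Series:
        return self.data[self.subject_col]

    @property
    def total_reads(self) -> Optional[np.ndarray]:
        if self.total_reads_col is None:
            return None
        return np.asarray(self.data[self.total_reads_col], dtype=float)


@dataclass
class ModelSpec:
    """Formulas and options defining one model fit.

    fixed_formula : right-hand-side formula for the mean model, e.g.
        ``"group + time + age"`` (the response is supplied separately).
    random_formula : ``"1 | subject"`` (random intercept) or
        ``"time | subject"`` (intercept + slope); ``None`` for no random
        effects (fixed-effects-only fits, mainly for diagnostics).
    zi_fixed_formula / zi_random_formula : zero-inflation part, only for
        methods ``zinb`` and ``zig``.
    correlation : within-subject residual correlation, one of ``none``,
        ``ar1``, ``cs`` (compound symmetry).
    offset_policy : ``log_total_reads`` adds log(T_ij) as an offset to the
        linear predictor of count models; must be ``none`` for
        proportion-transformed responses.
    method : one of ``nb``, ``zinb``, ``zig``, ``lmm``.
    """

    fixed_formula: str
    random_formula: Optional[str] = "1 | subject"
    zi_fixed_formula: Optional[str] = None
    zi_random_formula: Optional[str] = None
    correlation: str = "none"
    offset_policy: str = "log_total_reads"
    method: str = "nb"
    transform: Optional[str] = None  # zig only: log2count | asinsqrt | none

    def __post_init__(self) -> None:
        if self.method not in ("nb", "zinb", "zig", "lmm"):
            raise SpecificationError(f"unknown method {self.method!r}")
        if self.correlation not in ("none", "ar1", "cs", "compound_symmetry"):
            raise SpecificationError(f"unknown correlation {self.correlation!r}")
        if self.correlation == "compound_symmetry":
            self.correlation = "cs"
        if self.offset_policy not in ("log_total_reads", "none"):
            raise SpecificationError(f"unknown offset_policy {self.offset_policy!r}")
        if self.method not in ("zinb", "zig") and (
            self.zi_fixed_formula or self.zi_random_formula
        ):
            raise SpecificationError("zero-inflation formulas require method zinb or zig")


@dataclass
class FitResult:
    """Per-taxon fit summary: estimates, uncertainties, variance components.

    ``coef``/``se``/``pvalues`` are aligned Series over count-part
    (mean-model) fixed effects; the ``zero_*`` triple holds the
    zero-inflation part when the model has one.  ``dispersion`` is the NB
    shape theta for count families or the residual variance sigma^2 for the
    Gaussian family.
    """

    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    vc: Optional[pd.DataFrame] = None
    dispersion: float = np.nan
    zero_coef: Optional[pd.Series] = None
    zero_se: Optional[pd.Series] = None
    zero_pvalues: Optional[pd.Series] = None
    zero_vc: Optional[pd.DataFrame] = None
    converged: bool = True
    n_iter: int = 0
    method: str = ""
    warnings: list[str] = field(default_factory=list)
    loglik: float = np.nan
    loglik_trace: Optional[list[float]] = None
    aliased: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.se.values < 0):
            raise ValueError("standard errors must be non-negative")
        pv = self.pvalues.values
        if np.any((pv < 0) | (pv > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def has_zero_part(self) -> bool:
        return self.zero_coef is not None

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per coefficient, columns term/part/estimate/se/pvalue."""
        rows = [
            pd.DataFrame(
                {
                    "term": self.coef.index,
                    "part": "count",
                    "estimate": self.coef.values,
                    "se": self.se.values,
                    "pvalue": self.pvalues.values,
                }
            )
        ]
        if self.has_zero_part:
            rows.append(
                pd.DataFrame(
                    {
                        "term": self.zero_coef.index,
                        "part": "zero",
                        "estimate": self.zero_coef.values,
                        "se": self.zero_se.values,
                        "pvalue": self.zero_pvalues.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        """Human-readable coefficient tables, statsmodels-style."""
        lines = [f"Mixed model fit ({self.method}), "
                 f"{'converged' if self.converged else 'NOT converged'} "
                 f"in {self.n_iter} iterations"]
        tab = pd.DataFrame({"estimate": self.coef, "se": self.se, "pvalue": self.pvalues})
        lines.append("Fixed effects (count/mean part):")
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.has_zero_part:
            ztab = pd.DataFrame(
                {"estimate": self.zero_coef, "se": self.zero_se, "pvalue": self.zero_pvalues}
            )
            lines.append("Zero-inflation part:")
            lines.append(ztab.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.vc is not None:
            lines.append("Random-effect covariance:")
            lines.append(self.vc.to_string(float_format=lambda v: f"{v:.4g}"))
        lines.append(f"dispersion: {self.dispersion:.4g}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_taxa_table(
    path,
    orientation: str = "samples_by_taxa",
    scale: float = 1.0,
    is_proportion: bool = False,
) -> TaxaTable:
    """Read a delimited abundance table into a :class:`TaxaTable`.

    Parameters
    ----------
    orientation : ``samples_by_taxa`` or ``taxa_by_samples``; the latter is
        transposed on read so storage is always samples x taxa.
    scale : every entry is multiplied by this factor (e.g. 100 to put
        proportions on a percentage scale).  Scaling is always explicit.
    """
    df = _read_delimited(path)
    if orientation == "taxa_by_samples":
        df = df.T
    elif orientation != "samples_by_taxa":
        raise ValueError(f"unknown orientation {orientation!r}")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        for col in bad:
            nonnum = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            if len(nonnum):
                raise IntegrityError(
                    f"non-numeric cell in column {col!r}, row {nonnum.index[0]!r}: "
                    f"{nonnum.iloc[0]!r}"
                )
        df = df.astype(float)
    counts = df.values.astype(float) * float(scale)
    return TaxaTable(
        counts=counts,
        taxon_ids=list(map(str, df.columns)),
        sample_ids=list(map(str, df.index)),
        is_proportion=is_proportion,
    )


def read_sample_meta(
    path,
    subject_col: str = "subject",
    time_col: Optional[str] = "time",
    total_reads_col: Optional[str] = "total_reads",
) -> SampleMeta:
    """Read a delimited metadata table keyed by sample id."""
    df = _read_delimited(path)
    return SampleMeta(df, subject_col=subject_col, time_col=time_col,
                      total_reads_col=total_reads_col)


_RESULT_FLOAT_FMT = "%.12g"


def write_results_table(table: pd.DataFrame, path) -> None:
    """Write a long results table as TSV, numeric fields at 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format=_RESULT_FLOAT_FMT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def log2_transform(counts) -> np.ndarray:
    """y = log2(C + 1); zeros map to exactly 0."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("log2 transform requires non-negative input")
    return np.log2(c + 1.0)


def arcsine_sqrt_transform(counts, totals) -> np.ndarray:
    """y = arcsin(sqrt(C / T)) for proportions; range [0, pi/2], 0 maps to 0."""
    c = np.asarray(counts, dtype=float)
    t = np.asarray(totals, dtype=float)
    if np.any(c < 0):
        raise ValueError("arcsine-sqrt transform requires non-negative counts")
    if np.any(t <= 0):
        raise ValueError("totals must be positive")
    ratio = c / t
    if np.any(ratio > 1 + 1e-12):
        raise ValueError("count exceeds total in arcsine-sqrt transform")
    return np.arcsin(np.sqrt(np.clip(ratio, 0.0, 1.0)))


def nonzero_proportions(table: TaxaTable) -> pd.Series:
    """Fraction of strictly positive entries per taxon."""
    if table.n_samples == 0:
        raise ValueError("empty table")
    return pd.Series((table.counts > 0).mean(axis=0), index=table.taxon_ids)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignBundle:
    """Numeric design for one fit: everything the solvers need, row-aligned.

    Rows are grouped contiguously by subject and, when an AR(1) correlation
    is requested, ordered by time within subject; ``row_index`` maps back to
    positions in the original metadata order.
    """

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    groups: np.ndarray          # integer subject codes, contiguous blocks
    group_labels: list[str]
    Z: Optional[np.ndarray]     # random-effects design, n x q (or None)
    z_names: list[str]
    offset: np.ndarray
    order: np.ndarray           # observation position within subject (0-based)
    correlation: str
    zi_X: Optional[np.ndarray] = None
    zi_names: list[str] = field(default_factory=list)
    zi_Z: Optional[np.ndarray] = None
    zi_z_names: list[str] = field(default_factory=list)
    row_index: Optional[np.ndarray] = None
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_subjects(self) -> int:
        return len(self.group_labels)


def _split_random_formula(random_formula: str) -> tuple[str, str]:
    if "|" not in random_formula:
        raise SpecificationError(
            f"random formula {random_formula!r} must be of the form 'terms | group'"
        )
    lhs, grp = random_formula.rsplit("|", 1)
    return lhs.strip() or "1", grp.strip()


def _rhs_matrix(formula: str, df: pd.DataFrame, what: str):
    try:
        mat = patsy.dmatrix("~ " + formula, df, return_type="dataframe")
    except patsy.PatsyError as err:
        raise SpecificationError(f"cannot build {what} design: {err}") from None
    return mat


def build_design(
    meta: SampleMeta,
    spec: ModelSpec,
    response: np.ndarray,
) -> DesignBundle:
    """Assemble the design bundle for one response vector.

    Rows with missing values in any model variable are dropped (count
    recorded in ``n_dropped``).  Categorical covariates are expanded with
    the first-observed level as reference.  The offset is log(total_reads)
    under ``offset_policy='log_total_reads'`` and zero otherwise.
    """
    df = meta.data.copy()
    y = np.asarray(response, dtype=float)
    if len(y) != len(df):
        raise SpecificationError(
            f"response length {len(y)} does not match {len(df)} metadata rows"
        )
    df = df.reset_index(drop=True)

    # collect variables used anywhere in the model
    formulas = [spec.fixed_formula]
    rand_terms = rand_group = None
    if spec.random_formula:
        rand_terms, rand_group = _split_random_formula(spec.random_formula)
        formulas.append(rand_terms)
    else:
        rand_group = meta.subject_col
    zi_rand_terms = None
    if spec.zi_fixed_formula:
        formulas.append(spec.zi_fixed_formula)
    if spec.zi_random_formula:
        zi_rand_terms, zi_grp = _split_random_formula(spec.zi_random_formula)
        if zi_grp != rand_group:
            raise SpecificationError("zero-part random grouping must match the count part")
        formulas.append(zi_rand_terms)
    if rand_group not in df.columns:
        raise SpecificationError(f"grouping variable {rand_group!r} not in metadata")

    used: set[str] = {rand_group}
    for f in formulas:
        for name in patsy.ModelDesc.from_formula("~ " + f).rhs_termlist:
            for factor in name.factors:
                used.update(
                    v for v in _factor_vars(factor.code) if v in df.columns
                )
    if spec.offset_policy == "log_total_reads":
        if meta.total_reads_col is None:
            raise SpecificationError(
                "offset_policy='log_total_reads' but metadata has no total-reads column"
            )
        used.add(meta.total_reads_col)

    keep = ~df[sorted(used)].isna().any(axis=1) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].copy()
    y = y[keep]
    if len(df) == 0:
        raise SpecificationError("no rows left after dropping missing values")

    # deterministic ordering: contiguous subject blocks, by time within subject
    subj = df[rand_group].astype(str)
    subj_order = list(dict.fromkeys(subj))  # first-appearance order
    subj_rank = subj.map({s: i for i, s in enumerate(subj_order)})
    if meta.time_col is not None and meta.time_col in df.columns:
        sort_key = np.lexsort((df[meta.time_col].values, subj_rank.values))
    else:
        sort_key = np.argsort(subj_rank.values, kind="stable")
    df = df.iloc[sort_key]
    y = y[sort_key]
    row_index = np.flatnonzero(keep.values)[sort_key]

    groups = df[rand_group].astype(str).map({s: i for i, s in enumerate(subj_order)}).values
    order = np.zeros(len(df), dtype=int)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        order[idx] = np.arange(len(idx))

    Xdf = _rhs_matrix(spec.fixed_formula, df, "fixed-effects")
    X = Xdf.values
    x_names = [_clean_name(c) for c in Xdf.columns]

    Z = None
    z_names: list[str] = []
    if spec.random_formula:
        Zdf = _rhs_matrix(rand_terms, df, "random-effects")
        Z = Zdf.values
        z_names = [_clean_name(c) for c in Zdf.columns]

    if spec.offset_policy == "log_total_reads":
        totals = df[meta.total_reads_col].values.astype(float)
        if np.any(totals <= 0):
            raise SpecificationError("total_reads must be positive where an offset is used")
        offset = np.log(totals)
    else:
        offset = np.zeros(len(df))

    zi_X = zi_Z = None
    zi_names: list[str] = []
    zi_z_names: list[str] = []
    if spec.method in ("zinb", "zig"):
        zi_formula = spec.zi_fixed_formula or "1"
        Zidf = _rhs_matrix(zi_formula, df, "zero-part fixed")
        zi_X = Zidf.values
        zi_names = [_clean_name(c) for c in Zidf.columns]
        if spec.zi_random_formula:
            Zirdf = _rhs_matrix(zi_rand_terms, df, "zero-part random")
            zi_Z = Zirdf.values
            zi_z_names = [_clean_name(c) for c in Zirdf.columns]

    return DesignBundle(
        y=y, X=X, x_names=x_names,
        groups=groups, group_labels=subj_order,
        Z=Z, z_names=z_names,
        offset=offset, order=order,
        correlation=spec.correlation,
        zi_X=zi_X, zi_names=zi_names, zi_Z=zi_Z, zi_z_names=zi_z_names,
        row_index=row_index, n_dropped=n_dropped,
    )


def _factor_vars(code: str) -> list[str]:
    """Crude variable extraction from a patsy factor code."""
    import re

    return re.findall(r"[A-Za-z_][A-Za-z0-9_.]*", code)


def _clean_name(name: str) -> str:
    return name.replace("T.", "") if name.startswith("C(") else name
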