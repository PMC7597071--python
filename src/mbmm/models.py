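"""Model classes: the user-facing, statsmodels-flavored surface.

Each model family is a class built from a response vector plus a metadata
frame and formulas; ``fit()`` returns the :class:`~mbmm.data.FitResult`
carrying estimates, standard errors, p-values, variance components and a
``summary()`` table.

    >>> model = NBMM.from_dataframe(y, data, fixed="group + time + age",
    ...                             random="1 | subject")
    >>> result = model.fit()
    >>> print(result.summary())
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .data import (DesignBundle, FitResult, ModelSpec, SampleMeta,
                   build_design)
from .nbmm import FitControl, fit_nbmm
from .zigmm import fit_zigmm
from .zinbmm import fit_zinbmm

__all__ = ["NBMM", "ZINBMM", "ZIGMM"]


class _MixedModelBase:
    """Shared constructor/fit plumbing for the three model families."""

    method: str = ""

    def __init__(self, endog, meta: SampleMeta, spec: ModelSpec):
        if spec.method != self.method:
            spec = ModelSpec(
                fixed_formula=spec.fixed_formula,
                random_formula=spec.random_formula,
                zi_fixed_formula=spec.zi_fixed_formula,
                zi_random_formula=spec.zi_random_formula,
                correlation=spec.correlation,
                offset_policy=spec.offset_policy,
                method=self.method,
                transform=spec.transform,
            )
        self.spec = spec
        self.meta = meta
        self.endog = np.asarray(endog, dtype=float)
        self.design: DesignBundle = build_design(meta, spec, self.endog)

    @classmethod
    def from_dataframe(
        cls,
        endog,
        data: pd.DataFrame,
        fixed: str,
        random: Optional[str] = "1 | subject",
        zi_fixed: Optional[str] = None,
        zi_random: Optional[str] = None,
        correlation: str = "none",
        offset: str = "log_total_reads",
        subject_col: str = "subject",
        time_col: Optional[str] = "time",
        total_reads_col: Optional[str] = "total_reads",
        transform: Optional[str] = None,
    ):
        """Build the model from a metadata DataFrame and formula strings."""
        meta = SampleMeta(data, subject_col=subject_col, time_col=time_col,
                          total_reads_col=total_reads_col)
        spec = ModelSpec(
            fixed_formula=fixed, random_formula=random,
            zi_fixed_formula=zi_fixed, zi_random_formula=zi_random,
            correlation=correlation, offset_policy=offset,
            method=cls.method, transform=transform,
        )
        return cls(endog, meta, spec)

    def fit(self, control: Optional[FitControl] = None, **kwargs) -> FitResult:
        control = control or FitControl(**kwargs)
        return self._fit(control)

    def _fit(self, control: FitControl) -> FitResult:  # pragma: no cover
        raise NotImplementedError


class NBMM(_MixedModelBase):
    """Negative binomial mixed model for over-dispersed longitudinal counts."""

    method = "nb"

    def _fit(self, control: FitControl) -> FitResult:
        return fit_nbmm(self.design.y, self.design, control)


class ZINBMM(_MixedModelBase):
    """Zero-inflated NB mixed model for sparse over-dispersed counts."""

    method = "zinb"

    def _fit(self, control: FitControl) -> FitResult:
        return fit_zinbmm(self.design.y, self.design, control)


class ZIGMM(_MixedModelBase):
    """Zero-inflated Gaussian mixed model on transformed abundances.

    The response passed in is expected to be already transformed
    (log2(C+1) for counts, arcsin sqrt for proportions); the transformation
    helpers live in :mod:`mbmm.data`.
    """

    method = "zig"

    def _fit(self, control: FitControl) -> FitResult:
        return fit_zigmm(self.design.y, self.design, control)
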