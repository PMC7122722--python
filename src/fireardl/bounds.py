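"""Bounds test for a level (cointegrating) relationship.

The F statistic tests the joint null that every lagged-level coefficient in
the error-correction regression is zero (the lagged dependent level plus
all k lagged regressor levels, k+1 restrictions).  It is compared against
two asymptotic critical values: the lower bound assumes all regressors are
I(0), the upper assumes all are I(1).  F above the upper bound supports a
long-run relationship; below the lower bound, none; in between the test is
inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._critvals import BOUNDS_LEVELS, bounds_crit
from .ecm import EcmFit

__all__ = ["BoundsResult", "bounds_f_test", "critical_values", "decide"]


@dataclass
class BoundsResult:
    """Joint-levels F statistic with its bounds decision."""

    f_statistic: float
    k: int  # level regressors excluding the lagged dependent
    case: str
    level: float
    cv_lower: float  # all-I(0) bound
    cv_upper: float  # all-I(1) bound
    decision: str  # "cointegrated" | "inconclusive" | "no level relationship"
    n_restrictions: int

    def __post_init__(self) -> None:
        if self.cv_lower >= self.cv_upper:
            raise ValueError("lower bound must be below upper bound")
        if self.f_statistic < 0:
            raise ValueError("F statistic must be nonnegative")


def critical_values(k: int, case: str = "unrestricted_intercept", level: float = 0.05):
    """Published asymptotic bounds ``(cv_I0, cv_I1)`` for k level regressors."""
    return bounds_crit(k, level, case)


def decide(f_statistic: float, cvs: tuple[float, float]) -> str:
    """Trichotomous bounds decision from F and ``(cv_I0, cv_I1)``."""
    lo, hi = cvs
    if f_statistic > hi:
        return "cointegrated"
    if f_statistic < lo:
        return "no level relationship"
    return "inconclusive"


def bounds_f_test(
    fit: EcmFit, level: float = 0.05, case: str = "unrestricted_intercept"
) -> BoundsResult:
    """Wald F test that all lagged-level coefficients are jointly zero.

    F = (Rb)' [R V R']^{-1} (Rb) / q  with q = k+1 restrictions, V the OLS
    coefficient covariance.  Identical to the restricted-vs-unrestricted
    SSR comparison (tests verify the equivalence).
    """
    if level not in BOUNDS_LEVELS:
        raise ValueError(f"level must be one of {BOUNDS_LEVELS}")
    names = fit.ols.names
    level_cols = fit.design.level_columns
    missing = [c for c in level_cols if c not in names]
    if missing:
        raise ValueError(f"fit is missing level columns: {missing}")
    idx = [names.index(c) for c in level_cols]
    q = len(idx)
    b = fit.ols.params[idx]
    V = fit.ols.cov[np.ix_(idx, idx)]
    f_stat = float(b @ np.linalg.solve(V, b)) / q

    k = q - 1
    lo, hi = critical_values(k, case, level)
    return BoundsResult(
        f_statistic=f_stat,
        k=k,
        case=case,
        level=level,
        cv_lower=lo,
        cv_upper=hi,
        decision=decide(f_stat, (lo, hi)),
        n_restrictions=q,
    )
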