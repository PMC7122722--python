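"""Unit-root testing: augmented Dickey-Fuller and Phillips-Perron.

Bounds cointegration testing is only valid when every series is I(0) or
I(1) (never I(2)), so the first pipeline stage classifies each variable's
integration order.  The ADF auxiliary regression is

    dx_t = a0 + a1*t + lam*x_{t-1} + sum_{i=1..m} phi_i * dx_{t-i} + u_t

with the lag count m chosen by the Schwarz criterion, and the test
statistic is the t-ratio on the lagged level (left-tailed against
Dickey-Fuller critical values).  The Phillips-Perron variant keeps m=0 and
corrects the t-ratio nonparametrically with a Bartlett-kernel long-run
variance instead of lagged differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._critvals import dickey_fuller_crit
from ._ols import OlsFit, ols

__all__ = [
    "UnitRootResult",
    "adf_test",
    "pp_test",
    "classify_integration_order",
    "IntegrationOrderError",
]


@dataclass
class UnitRootResult:
    """Outcome of a single unit-root test on one series."""

    variable: str
    test: str  # "ADF" | "PP"
    deterministic: str  # "n" | "c" | "ct"
    statistic: float
    crit_values: dict[float, float]  # level -> critical value
    lags: int  # ADF: chosen m; PP: Bartlett bandwidth
    aux: OlsFit
    level: float = 0.05
    order_tested: str = "level"  # "level" | "1st diff" | "2nd diff"

    def __post_init__(self) -> None:
        cvs = [self.crit_values[l] for l in sorted(self.crit_values)]
        if not all(a < b for a, b in zip(cvs, cvs[1:])):
            raise ValueError("critical values must be strictly ordered (left tail)")

    @property
    def stationary(self) -> bool:
        """Reject the unit-root null at the configured level."""
        return self.statistic < self.crit_values[self.level]

    @property
    def decision(self) -> str:
        return "stationary" if self.stationary else "nonstationary"


def _validate_series(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"series too short ({x.size} < {min_len})")
    if np.ptp(x) == 0:
        raise ValueError("series is constant (zero variance)")
    return x


def _df_design(x: np.ndarray, m: int, deterministic: str, t_offset: int = 0):
    """Design for the Dickey-Fuller regression with m lagged differences.

    Rows start at index m+1 of the differenced series so that all lags are
    defined.  Returns (y, X, names) for the sample of length n-1-m.
    """
    dx = np.diff(x)
    n = dx.size  # usable differences
    rows = np.arange(m, n)
    y = dx[rows]
    cols = []
    names = []
    if deterministic in ("c", "ct"):
        cols.append(np.ones(rows.size))
        names.append("const")
    if deterministic == "ct":
        cols.append(rows.astype(float) + 1.0 + t_offset)
        names.append("trend")
    cols.append(x[rows])  # x_{t-1}
    names.append("level")
    for i in range(1, m + 1):
        cols.append(dx[rows - i])
        names.append(f"dlag{i}")
    return y, np.column_stack(cols), names


def adf_test(
    series,
    deterministic: str = "ct",
    max_lag: int | None = None,
    ic: str = "sic",
    variable: str = "x",
    level: float = 0.05,
    order_tested: str = "level",
) -> UnitRootResult:
    """Augmented Dickey-Fuller test with Schwarz-criterion lag selection.

    All candidate lag counts 0..max_lag are scored on the common sample
    that drops the first ``max_lag`` differences (so their information
    criteria are comparable), then the winning m is refit on the longest
    sample it allows.  ``max_lag`` defaults to the Schwert rule
    ``floor(12 * (n/100)^(1/4))``.
    """
    if ic != "sic":
        raise ValueError("only Schwarz-criterion lag selection is supported")
    x = np.asarray(series, dtype=float).ravel()
    if max_lag is None:
        max_lag = int(np.floor(12.0 * (x.size / 100.0) ** 0.25))
        max_lag = min(max_lag, max(0, (x.size - 15) // 2))
    x = _validate_series(x, max_lag + 12)

    best_m, best_sic = 0, np.inf
    for m in range(max_lag + 1):
        y, X, names = _df_design(x, max_lag, deterministic)
        keep = [i for i, nm in enumerate(names) if not nm.startswith("dlag") or int(nm[4:]) <= m]
        fit = ols(y, X[:, keep], [names[i] for i in keep], keep_data=False)
        T = fit.nobs
        sic = np.log(fit.ssr / T) + len(keep) * np.log(T) / T
        if sic < best_sic - 1e-12:
            best_sic, best_m = sic, m

    y, X, names = _df_design(x, best_m, deterministic)
    fit = ols(y, X, names)
    i = names.index("level")
    stat = float(fit.params[i] / fit.bse[i])
    cvs = dickey_fuller_crit(fit.nobs, deterministic)
    return UnitRootResult(
        variable=variable,
        test="ADF",
        deterministic=deterministic,
        statistic=stat,
        crit_values=cvs,
        lags=best_m,
        aux=fit,
        level=level,
        order_tested=order_tested,
    )


def pp_test(
    series,
    deterministic: str = "ct",
    bandwidth: int | None = None,
    variable: str = "x",
    level: float = 0.05,
    order_tested: str = "level",
) -> UnitRootResult:
    """Phillips-Perron test (Z-tau statistic).

    Fits the Dickey-Fuller regression without lagged differences, then
    corrects the t-ratio for residual serial correlation using a Bartlett
    long-run variance with bandwidth ``floor(4 * (n/100)^(2/9))`` by
    default.
    """
    x = _validate_series(np.asarray(series, dtype=float).ravel(), 15)
    y, X, names = _df_design(x, 0, deterministic)
    fit = ols(y, X, names)
    T = fit.nobs
    if bandwidth is None:
        bandwidth = int(np.floor(4.0 * (T / 100.0) ** (2.0 / 9.0)))
    u = fit.resid
    gamma0 = float(u @ u) / T
    lam2 = gamma0
    for j in range(1, bandwidth + 1):
        gj = float(u[j:] @ u[:-j]) / T
        lam2 += 2.0 * (1.0 - j / (bandwidth + 1.0)) * gj
    lam2 = max(lam2, 1e-12 * gamma0)

    i = names.index("level")
    t_rho = float(fit.params[i] / fit.bse[i])
    se_rho = float(fit.bse[i])
    s = np.sqrt(fit.sigma2)
    # Z-tau correction (vanishes when residuals are serially uncorrelated)
    stat = np.sqrt(gamma0 / lam2) * t_rho - (lam2 - gamma0) / (2.0 * np.sqrt(lam2)) * (
        T * se_rho / s
    )
    cvs = dickey_fuller_crit(T, deterministic)
    return UnitRootResult(
        variable=variable,
        test="PP",
        deterministic=deterministic,
        statistic=float(stat),
        crit_values=cvs,
        lags=bandwidth,
        aux=fit,
        level=level,
        order_tested=order_tested,
    )


class IntegrationOrderError(ValueError):
    """Raised when a series is not stationary even after two differences."""


def classify_integration_order(
    level: UnitRootResult, diff1: UnitRootResult, diff2: UnitRootResult | None = None
) -> int:
    """Smallest differencing order at which the test rejects the unit root.

    Returns d in {0, 1, 2}.  d=2 invalidates bounds testing downstream, so
    callers should treat it as a flag; nonstationarity at every tested
    order raises :class:`IntegrationOrderError`.
    """
    results = [level, diff1] + ([diff2] if diff2 is not None else [])
    names = {r.variable for r in results}
    tests = {r.test for r in results}
    if len(names) > 1 or len(tests) > 1:
        raise ValueError("all results must concern the same variable and test")
    for d, res in enumerate(results):
        if res.stationary:
            return d
    raise IntegrationOrderError(
        f"{level.variable}: not stationary at any tested order (order > {len(results) - 1})"
    )
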