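"""Residual, stability and seasonal diagnostics for the fitted models.

Covers the standard post-estimation battery: Durbin-Watson, the ARCH LM
test for conditional heteroskedasticity, Breusch-Godfrey for residual
autocorrelation, Ramsey RESET for functional form, Jarque-Bera for
normality, and the Brown-Durbin-Evans CUSUM / CUSUM-of-squares recursive
stability tests.  Also the pooled seasonal Pearson correlations between
area burned and each climate variable over the FMA / MJJ / ASO month
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._critvals import cusumsq_crit
from ._ols import ols
from .dataset import TimeSeriesDataset
from .ecm import EcmFit

__all__ = [
    "durbin_watson",
    "arch_lm",
    "breusch_godfrey",
    "ramsey_reset",
    "jarque_bera",
    "cusum",
    "CusumResult",
    "seasonal_correlations",
    "SeasonalCorrelation",
    "DiagnosticsReport",
    "diagnostics_report",
]

SEASON_GROUPS = {"FMA": (2, 3, 4), "MJJ": (5, 6, 7), "ASO": (8, 9, 10)}


def durbin_watson(residuals) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all residuals are zero")
    return float(np.sum(np.diff(e) ** 2) / denom)


def arch_lm(residuals, lags: int = 1) -> tuple[float, float]:
    """Engle's LM test: regress e_t^2 on its lags; T*R^2 ~ chi2(lags)."""
    e = np.asarray(residuals, dtype=float).ravel()
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if e.size <= lags + 2:
        raise ValueError("too few residuals for the requested lags")
    e2 = e**2
    if np.ptp(e2) == 0:
        raise ValueError("squared residuals are constant")
    y = e2[lags:]
    X = np.column_stack([np.ones(y.size)] + [e2[lags - j : -j] for j in range(1, lags + 1)])
    fit = ols(y, X, keep_data=False)
    T = y.size
    stat = T * fit.r2
    return float(stat), float(stats.chi2.sf(stat, lags))


def breusch_godfrey(fit: EcmFit, lags: int = 1) -> tuple[float, float]:
    """LM test for serial correlation of the regression errors.

    Auxiliary regression of the residuals on the original design plus
    ``lags`` zero-padded lagged residuals; statistic (T - lags) * R^2
    against chi2(lags).
    """
    if lags < 1:
        raise ValueError("lags must be >= 1")
    e = fit.ols.resid
    X = fit.ols.X
    T = e.size
    if T <= X.shape[1] + lags + 2:
        raise ValueError("too few observations for the auxiliary regression")
    lagged = np.column_stack(
        [np.concatenate([np.zeros(j), e[:-j]]) for j in range(1, lags + 1)]
    )
    aux = ols(e, np.column_stack([X, lagged]), keep_data=False)
    stat = (T - lags) * aux.r2
    return float(stat), float(stats.chi2.sf(stat, lags))


def ramsey_reset(fit: EcmFit, powers=(2, 3)) -> tuple[float, float]:
    """RESET: F test on powers of the fitted values added to the design."""
    yhat = fit.ols.fitted
    if np.ptp(yhat) == 0:
        raise ValueError("fitted values are constant")
    scale = float(np.max(np.abs(yhat)))
    z = yhat / scale  # rescale to keep the augmented design well conditioned
    X = fit.ols.X
    y = fit.ols.y
    aug = np.column_stack([X] + [z**p for p in powers])
    unres = ols(y, aug, keep_data=False)
    q = len(powers)
    df2 = unres.df_resid
    f = ((fit.ols.ssr - unres.ssr) / q) / (unres.ssr / df2)
    return float(f), float(stats.f.sf(f, q, df2))


def jarque_bera(residuals) -> tuple[float, float, float, float]:
    """JB = n/6 (S^2 + (K-3)^2/4); returns (stat, p, skewness, excess kurtosis)."""
    e = np.asarray(residuals, dtype=float).ravel()
    if e.size < 8:
        raise ValueError("need at least 8 residuals")
    sd = e.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance residuals")
    z = (e - e.mean()) / sd
    S = float(np.mean(z**3))
    K = float(np.mean(z**4))
    stat = e.size / 6.0 * (S**2 + (K - 3.0) ** 2 / 4.0)
    return float(stat), float(stats.chi2.sf(stat, 2)), S, K - 3.0


@dataclass
class CusumResult:
    """Recursive-residual stability paths with 5% bounds."""

    recursive_residuals: np.ndarray  # w_r, r = k+1..T
    cusum: np.ndarray
    cusum_lower: np.ndarray
    cusum_upper: np.ndarray
    cusum_within: bool
    cusumsq: np.ndarray
    cusumsq_lower: np.ndarray
    cusumsq_upper: np.ndarray
    cusumsq_within: bool
    steps: np.ndarray  # observation index r of each path point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "cusum": self.cusum,
                "cusum_lower": self.cusum_lower,
                "cusum_upper": self.cusum_upper,
                "cusumsq": self.cusumsq,
                "cusumsq_lower": self.cusumsq_lower,
                "cusumsq_upper": self.cusumsq_upper,
            }
        )


def recursive_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Standardized one-step-ahead prediction errors from expanding fits.

    w_r = (y_r - x_r' b_{r-1}) / sqrt(1 + x_r' (X_{r-1}'X_{r-1})^{-1} x_r)
    for r = k+1 .. T (zero-based: rows k..T-1).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T, k = X.shape
    if T <= k + 2:
        raise ValueError("too few observations for recursive residuals")
    w = np.empty(T - k)
    xtx = X[:k].T @ X[:k]
    xty = X[:k].T @ y[:k]
    for r in range(k, T):
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient recursive update at step {r}") from exc
        b = xtx_inv @ xty
        x_r = X[r]
        denom = 1.0 + float(x_r @ xtx_inv @ x_r)
        w[r - k] = (y[r] - float(x_r @ b)) / np.sqrt(denom)
        xtx += np.outer(x_r, x_r)
        xty += x_r * y[r]
    return w


def cusum(fit: EcmFit, level: float = 0.05) -> CusumResult:
    """CUSUM and CUSUMSQ stability paths from recursive residuals.

    CUSUM bounds are the Brown-Durbin-Evans 5% straight lines
    ``+/- 0.948 [sqrt(T-k) + 2 (r-k)/sqrt(T-k)]``; CUSUMSQ bounds are the
    expectation line (r-k)/(T-k) offset by the embedded 5% critical value.
    """
    if level != 0.05:
        raise ValueError("only 5% stability bounds are embedded")
    y, X = fit.ols.y, fit.ols.X
    T, k = X.shape
    w = recursive_residuals(y, X)
    m = w.size  # T - k
    sw = np.sqrt(np.sum((w - w.mean()) ** 2) / (m - 1))
    cs = np.cumsum(w) / sw
    r = np.arange(1, m + 1)
    bound = 0.948 * (np.sqrt(m) + 2.0 * r / np.sqrt(m))
    csq = np.cumsum(w**2) / np.sum(w**2)
    c0 = cusumsq_crit(m)
    line = r / m
    return CusumResult(
        recursive_residuals=w,
        cusum=cs,
        cusum_lower=-bound,
        cusum_upper=bound,
        cusum_within=bool(np.all(np.abs(cs) <= bound)),
        cusumsq=csq,
        cusumsq_lower=np.clip(line - c0, 0.0, 1.0),
        cusumsq_upper=np.clip(line + c0, 0.0, 1.0),
        cusumsq_within=bool(np.all(np.abs(csq - line) <= c0)),
        steps=np.arange(k, T),
    )


@dataclass
class SeasonalCorrelation:
    """Pooled Pearson correlations per season group (Table-6 shape)."""

    r: pd.DataFrame  # index: group; columns: variables
    p: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.r.copy()
        for col in out.columns:
            out[col] = [
                f"{rv:.3f} ({pv:.3f})" if np.isfinite(rv) else "NA"
                for rv, pv in zip(self.r[col], self.p[col])
            ]
        return out


def seasonal_correlations(
    ds: TimeSeriesDataset,
    response: str = "area_burned",
    groups: dict[str, tuple[int, ...]] | None = None,
) -> SeasonalCorrelation:
    """Pearson r between the response and every other variable by season.

    Months are pooled within each group (e.g. all Feb/Mar/Apr rows) before
    correlating.  Zero-variance cells are reported as missing rather than
    raising.
    """
    groups = groups or SEASON_GROUPS
    others = [v for v in ds.variables if v != response]
    rmat, pmat = {}, {}
    month = ds.frame.index.month
    for gname, months in groups.items():
        mask = np.isin(month, months)
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 observations in group {gname}")
        sub = ds.frame.loc[mask]
        rrow, prow = [], []
        yv = sub[response].to_numpy(dtype=float)
        for v in others:
            xv = sub[v].to_numpy(dtype=float)
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rrow.append(np.nan)
                prow.append(np.nan)
                continue
            r, p = stats.pearsonr(yv, xv)
            rrow.append(float(r))
            prow.append(float(p))
        rmat[gname] = rrow
        pmat[gname] = prow
    r = pd.DataFrame.from_dict(rmat, orient="index", columns=others)
    p = pd.DataFrame.from_dict(pmat, orient="index", columns=others)
    return SeasonalCorrelation(r=r, p=p)


@dataclass
class DiagnosticsReport:
    """The full diagnostic battery for one fitted model."""

    durbin_watson: float
    arch_lm: tuple[float, float]
    breusch_godfrey: tuple[float, float]
    ramsey_reset: tuple[float, float]
    jarque_bera: tuple[float, float, float, float]
    cusum: CusumResult

    def to_dict(self) -> dict:
        return {
            "durbin_watson": self.durbin_watson,
            "arch_lm_stat": self.arch_lm[0],
            "arch_lm_p": self.arch_lm[1],
            "breusch_godfrey_stat": self.breusch_godfrey[0],
            "breusch_godfrey_p": self.breusch_godfrey[1],
            "ramsey_reset_stat": self.ramsey_reset[0],
            "ramsey_reset_p": self.ramsey_reset[1],
            "jarque_bera_stat": self.jarque_bera[0],
            "jarque_bera_p": self.jarque_bera[1],
            "cusum_within_bounds": self.cusum.cusum_within,
            "cusumsq_within_bounds": self.cusum.cusumsq_within,
        }


def diagnostics_report(fit: EcmFit, arch_lags: int = 1, bg_lags: int = 1) -> DiagnosticsReport:
    """Run the whole battery on one fit."""
    return DiagnosticsReport(
        durbin_watson=durbin_watson(fit.ols.resid),
        arch_lm=arch_lm(fit.ols.resid, arch_lags),
        breusch_godfrey=breusch_godfrey(fit, bg_lags),
        ramsey_reset=ramsey_reset(fit),
        jarque_bera=jarque_bera(fit.ols.resid),
        cusum=cusum(fit),
    )
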