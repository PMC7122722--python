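"""Minimal ordinary-least-squares core shared by every regression stage.

All estimators in this package (unit-root auxiliary regressions, the
error-correction model, diagnostic auxiliary regressions) reduce to OLS on
an explicit design matrix, so a single well-tested solver keeps the numerics
in one place.  The solver uses a QR-based least-squares route
(``numpy.linalg.lstsq``); tests compare it against independent
normal-equations solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OlsFit", "ols"]


@dataclass
class OlsFit:
    """Result of an OLS fit ``y = X b + e``.

    Attributes
    ----------
    params : (k,) coefficient estimates, ordered as the design columns.
    cov : (k, k) coefficient covariance ``s^2 (X'X)^{-1}`` with
        ``s^2 = SSR / (n - k)``.
    resid : (n,) residuals.
    fitted : (n,) fitted values.
    ssr : sum of squared residuals.
    sigma2 : ``s^2`` residual variance estimate.
    r2, adj_r2 : coefficient of determination (centred when the design
        contains a constant) and its degrees-of-freedom adjustment.
    names : design column names.
    """

    params: np.ndarray
    cov: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    ssr: float
    sigma2: float
    r2: float
    adj_r2: float
    nobs: int
    df_resid: int
    names: list[str] = field(default_factory=list)
    X: np.ndarray | None = None
    y: np.ndarray | None = None

    @property
    def bse(self) -> np.ndarray:
        """Coefficient standard errors."""
        return np.sqrt(np.diag(self.cov))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse


def ols(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    *,
    keep_data: bool = True,
) -> OlsFit:
    """Fit OLS and return coefficient, covariance and fit statistics.

    Raises
    ------
    ValueError
        If the design is rank deficient (dependent columns are named in
        the message) or shapes disagree.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} rows but X has {n}")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    if names is None:
        names = [f"x{i}" for i in range(k)]

    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # identify a maximal independent set via pivoted QR to name offenders
        _, _, piv = _pivoted_qr(X)
        dropped = sorted(piv[rank:])
        bad = ", ".join(names[i] for i in dropped)
        raise ValueError(f"design matrix is rank deficient; dependent columns: {bad}")

    params, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ params
    resid = y - fitted
    ssr = float(resid @ resid)
    df_resid = n - k
    sigma2 = ssr / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry

    has_const = np.any(np.all(np.isclose(X, X[0, :]), axis=0) & (np.abs(X[0, :]) > 0))
    tss = float(((y - y.mean()) ** 2).sum()) if has_const else float(y @ y)
    r2 = 1.0 - ssr / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if has_const else r2

    return OlsFit(
        params=params,
        cov=cov,
        resid=resid,
        fitted=fitted,
        ssr=ssr,
        sigma2=sigma2,
        r2=r2,
        adj_r2=adj_r2,
        nobs=n,
        df_resid=df_resid,
        names=list(names),
        X=X if keep_data else None,
        y=y if keep_data else None,
    )


def _pivoted_qr(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, mode="economic", pivoting=True)
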