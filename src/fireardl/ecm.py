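"""ARDL estimation in error-correction form and long-/short-run elasticities.

The conditional error-correction regression for a response ``y`` and
regressors ``x_1..x_k`` (all in logs) is

    dy_t = a0 + th0*y_{t-1} + sum_k th_k*x_{k,t-1}
         + sum_{i=1..p-1} a_i*dy_{t-i}
         + sum_k sum_{j=0..q_k} b_{k,j}*dx_{k,t-j} + e_t

Estimated by OLS.  The long-run elasticity of regressor k is
``-th_k / th0`` (finite and meaningful when th0 < 0, the error-correction
condition); its standard error comes from the delta method.  The
coefficient th0 itself is the error-correction term ECM(-1): the fraction
of a disequilibrium corrected each month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import OlsFit, ols
from .dataset import TimeSeriesDataset

__all__ = [
    "EcmSpec",
    "EcmFit",
    "LongRunResult",
    "ShortRunResult",
    "build_ecm_design",
    "fit_ecm",
    "long_run_coefficients",
    "short_run_coefficients",
    "rotate_models",
]


@dataclass(frozen=True)
class EcmSpec:
    """Which variable responds, to which regressors, with which lag orders."""

    dependent: str
    regressors: tuple[str, ...]
    p: int = 1  # autoregressive order of the dependent variable
    q: dict[str, int] | None = None  # per-regressor difference-lag order
    constant: bool = True

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if len(set(self.regressors)) != len(self.regressors):
            raise ValueError("duplicate regressor names")
        if self.dependent in self.regressors:
            raise ValueError("dependent variable cannot also be a regressor")
        q = dict(self.q or {})
        for k, v in q.items():
            if v < 0:
                raise ValueError(f"q[{k!r}] must be >= 0")
        object.__setattr__(self, "q", q)

    def q_for(self, name: str) -> int:
        return self.q.get(name, 1)

    @property
    def order_string(self) -> str:
        return "(" + ",".join([str(self.p)] + [str(self.q_for(r)) for r in self.regressors]) + ")"


@dataclass
class EcmDesign:
    """Materialised regression arrays with column bookkeeping."""

    y: np.ndarray  # dy_t
    X: np.ndarray
    names: list[str]
    index: pd.PeriodIndex  # rows retained
    level_columns: list[str]  # lagged dependent + lagged regressor levels
    spec: EcmSpec


def build_ecm_design(ds: TimeSeriesDataset, spec: EcmSpec) -> EcmDesign:
    """Assemble the error-correction design matrix.

    Column order: constant, y_{t-1}, x_{k,t-1} in regressor order, lagged
    dy terms, then dx_{k,t-j} blocks (j = 0..q_k).  Rows whose lags reach
    before the sample are dropped.
    """
    for v in (spec.dependent, *spec.regressors):
        if v not in ds.variables:
            raise KeyError(f"variable {v!r} not in dataset")

    f = ds.frame
    y = f[spec.dependent]
    cols: dict[str, pd.Series] = {}
    target = y.diff()
    if spec.constant:
        cols["const"] = pd.Series(1.0, index=f.index)
    cols[f"L.{spec.dependent}"] = y.shift(1)
    for r in spec.regressors:
        cols[f"L.{r}"] = f[r].shift(1)
    for i in range(1, spec.p):
        cols[f"LD{i}.{spec.dependent}"] = y.diff().shift(i)
    for r in spec.regressors:
        for j in range(spec.q_for(r) + 1):
            cols[f"D.{r}" if j == 0 else f"L{j}D.{r}"] = f[r].diff().shift(j)

    design = pd.DataFrame(cols)
    mask = design.notna().all(axis=1) & target.notna()
    design, target = design.loc[mask], target.loc[mask]
    names = list(design.columns)
    level_cols = [f"L.{spec.dependent}"] + [f"L.{r}" for r in spec.regressors]
    return EcmDesign(
        y=target.to_numpy(dtype=float),
        X=design.to_numpy(dtype=float),
        names=names,
        index=design.index,
        level_columns=level_cols,
        spec=spec,
    )


@dataclass
class EcmFit:
    """Estimated error-correction regression."""

    spec: EcmSpec
    design: EcmDesign
    ols: OlsFit

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.ols.names, self.ols.params))

    @property
    def cov(self) -> np.ndarray:
        return self.ols.cov

    @property
    def resid(self) -> np.ndarray:
        return self.ols.resid

    @property
    def r2(self) -> float:
        return self.ols.r2

    @property
    def adj_r2(self) -> float:
        return self.ols.adj_r2

    @property
    def ssr(self) -> float:
        return self.ols.ssr

    @property
    def nobs(self) -> int:
        return self.ols.nobs

    @property
    def durbin_watson(self) -> float:
        e = self.ols.resid
        return float(np.sum(np.diff(e) ** 2) / np.sum(e**2))

    @property
    def sample(self) -> tuple[str, str]:
        return str(self.design.index[0]), str(self.design.index[-1])

    @property
    def ect(self) -> float:
        """Coefficient on the lagged dependent level (error-correction term)."""
        return self.params[f"L.{self.spec.dependent}"]

    def name_index(self, name: str) -> int:
        return self.ols.names.index(name)


def fit_ecm(ds: TimeSeriesDataset, spec: EcmSpec) -> EcmFit:
    """Least-squares fit of the error-correction regression."""
    design = build_ecm_design(ds, spec)
    fit = ols(design.y, design.X, design.names)
    return EcmFit(spec=spec, design=design, ols=fit)


@dataclass
class LongRunRow:
    regressor: str
    elasticity: float
    se: float
    p_value: float


@dataclass
class LongRunResult:
    """Long-run (equilibrium) elasticities ``-th_k/th0`` with delta-method SEs."""

    rows: list[LongRunRow]
    ect: float
    no_error_correction: bool  # th0 >= 0: no converging equilibrium
    fit: EcmFit

    def __getitem__(self, regressor: str) -> LongRunRow:
        for row in self.rows:
            if row.regressor == regressor:
                return row
        raise KeyError(regressor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regressor": [r.regressor for r in self.rows],
                "elasticity": [r.elasticity for r in self.rows],
                "se": [r.se for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
            }
        )


def long_run_coefficients(fit: EcmFit) -> LongRunResult:
    """Long-run elasticities from the level coefficients.

    ``th0 >= 0`` flags the absence of error correction; elasticities are
    still reported (with the flag) so a misbehaving fit remains
    inspectable.
    """
    spec = fit.spec
    i0 = fit.name_index(f"L.{spec.dependent}")
    th0 = float(fit.ols.params[i0])
    rows = []
    for r in spec.regressors:
        ik = fit.name_index(f"L.{r}")
        thk = float(fit.ols.params[ik])
        elast = -thk / th0
        # delta method on g(th0, thk) = -thk/th0
        g = np.array([thk / th0**2, -1.0 / th0])
        sub = fit.ols.cov[np.ix_([i0, ik], [i0, ik])]
        var = float(g @ sub @ g)
        se = math.sqrt(max(var, 0.0))
        z = elast / se if se > 0 else np.inf
        p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
        rows.append(LongRunRow(regressor=r, elasticity=elast, se=se, p_value=p))
    return LongRunResult(rows=rows, ect=th0, no_error_correction=th0 >= 0, fit=fit)


@dataclass
class ShortRunRow:
    regressor: str
    coefficient: float
    se: float
    p_value: float


@dataclass
class ShortRunResult:
    """Contemporaneous difference coefficients plus the ECM(-1) term."""

    rows: list[ShortRunRow]
    ect: float
    ect_se: float
    ect_p_value: float
    stable: bool  # ECT in (-2, 0) keeps the recursion convergent
    fit: EcmFit

    def __getitem__(self, regressor: str) -> ShortRunRow:
        for row in self.rows:
            if row.regressor == regressor:
                return row
        raise KeyError(regressor)


def short_run_coefficients(fit: EcmFit) -> ShortRunResult:
    """Short-run elasticities (coefficients on dx_t) and ECM(-1)."""
    spec = fit.spec
    i0 = fit.name_index(f"L.{spec.dependent}")
    th0 = float(fit.ols.params[i0])
    th0_se = float(fit.ols.bse[i0])
    dfres = fit.ols.df_resid
    p0 = 2.0 * stats.t.sf(abs(th0 / th0_se), dfres) if th0_se > 0 else 0.0
    rows = []
    for r in spec.regressors:
        ik = fit.name_index(f"D.{r}")
        b = float(fit.ols.params[ik])
        se = float(fit.ols.bse[ik])
        p = 2.0 * stats.t.sf(abs(b / se), dfres) if se > 0 else 0.0
        rows.append(ShortRunRow(regressor=r, coefficient=b, se=se, p_value=p))
    return ShortRunResult(
        rows=rows,
        ect=th0,
        ect_se=th0_se,
        ect_p_value=float(p0),
        stable=-2.0 < th0 < 0.0,
        fit=fit,
    )


def rotate_models(ds: TimeSeriesDataset, base_spec: EcmSpec) -> dict[str, EcmFit]:
    """Fit one error-correction model per variable as the dependent.

    Each rotation keeps the base lag orders by variable name (a variable
    without a recorded order gets the default q=1).  Returns fits keyed by
    dependent-variable name, in dataset variable order.
    """
    variables = [base_spec.dependent, *base_spec.regressors]
    fits: dict[str, EcmFit] = {}
    for dep in variables:
        regs = tuple(v for v in variables if v != dep)
        q = {r: base_spec.q_for(r) for r in regs if r != base_spec.dependent}
        spec = EcmSpec(dependent=dep, regressors=regs, p=base_spec.p, q=q, constant=base_spec.constant)
        fits[dep] = fit_ecm(ds, spec)
    return fits
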