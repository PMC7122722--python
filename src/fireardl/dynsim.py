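"""Stochastic counterfactual simulation of a fitted error-correction model.

To express what a fitted model implies for fire extent, the coefficient
vector is drawn repeatedly from its estimated sampling distribution
MVN(b_hat, V_hat); for each draw the ECM recursion is iterated with all
regressors pinned at their sample means, a permanent shift is applied to
one regressor at the shock time, and the response path is recorded.  The
spread of paths across draws gives nested 75/90/95% uncertainty bands
around the mean counterfactual response.

In the default expected-values mode no residual noise is injected, so each
path converges geometrically (rate 1 + th0) to the new equilibrium and the
mean terminal response to a +1 log-unit shock equals the draw-averaged
long-run elasticity.  Predicted-values mode adds N(0, s^2) regression
noise each period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecm import EcmFit

__all__ = ["ShockScenario", "SimulationPaths", "simulate_response", "summarize_bands"]


@dataclass(frozen=True)
class ShockScenario:
    """A permanent shift applied to one regressor mid-simulation."""

    shocked: str
    size: float = 1.0  # in SD multiples of the shocked series (or log units)
    size_unit: str = "sd"  # "sd" | "log"
    shock_time: int = 10  # periods after burn-in
    horizon: int = 20
    burn_in: int = 20
    n_sims: int = 5000
    mode: str = "expected"  # "expected" | "predicted"
    permanent: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if not (0 <= self.shock_time < self.horizon):
            raise ValueError("shock time must fall inside the horizon")
        if self.mode not in ("expected", "predicted"):
            raise ValueError("mode must be 'expected' or 'predicted'")
        if self.size_unit not in ("sd", "log"):
            raise ValueError("size_unit must be 'sd' or 'log'")


@dataclass
class SimulationPaths:
    """Simulated response trajectories and their percentile bands."""

    paths: np.ndarray  # n_kept x (burn_in + horizon) levels of the response
    time: np.ndarray  # period index, 0 = first burn-in period
    shock_period: int  # absolute index of the shock
    scenario: ShockScenario
    bands: pd.DataFrame  # period, mean, lo/hi at 75/90/95
    n_divergent: int  # draws excluded because th0 >= 0
    shock_log_units: float = 0.0

    @property
    def exclusion_rate(self) -> float:
        total = self.paths.shape[0] + self.n_divergent
        return self.n_divergent / total if total else 0.0

    @property
    def mean_path(self) -> np.ndarray:
        return self.bands["mean"].to_numpy()


def summarize_bands(paths: np.ndarray, levels=(0.75, 0.90, 0.95)) -> pd.DataFrame:
    """Per-period empirical quantile bands at the given central coverages."""
    paths = np.asarray(paths, dtype=float)
    if paths.size == 0:
        raise ValueError("empty path matrix")
    for lv in levels:
        if not 0.0 < lv < 1.0:
            raise ValueError(f"band level {lv} outside (0, 1)")
    out = {"period": np.arange(paths.shape[1]), "mean": paths.mean(axis=0)}
    for lv in levels:
        lo, hi = (1.0 - lv) / 2.0, (1.0 + lv) / 2.0
        pct = int(round(lv * 100))
        out[f"lo{pct}"] = np.quantile(paths, lo, axis=0)
        out[f"hi{pct}"] = np.quantile(paths, hi, axis=0)
    return pd.DataFrame(out)


def simulate_response(
    fit: EcmFit, scenario: ShockScenario, ds=None
) -> SimulationPaths:
    """Trace the response distribution of the dependent variable to a shock.

    Parameter draws with a nonnegative error-correction coefficient cannot
    converge; they are excluded from the bands and counted in
    ``n_divergent`` (never silently dropped).
    """
    rng = np.random.default_rng(scenario.seed)
    spec = fit.spec
    if scenario.shocked not in spec.regressors:
        raise KeyError(f"shocked variable {scenario.shocked!r} is not a regressor")

    b_hat = fit.ols.params
    V = fit.ols.cov
    # guard: covariance must be PSD for MVN draws
    w = np.linalg.eigvalsh(V)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        raise ValueError("coefficient covariance is not positive semidefinite")
    draws = rng.multivariate_normal(b_hat, V, size=scenario.n_sims, method="svd")

    names = fit.ols.names
    i_th0 = names.index(f"L.{spec.dependent}")
    i_const = names.index("const") if "const" in names else None
    xbar = {r: float(np.mean(fit.design.X[:, names.index(f"L.{r}")])) for r in spec.regressors}

    if scenario.size_unit == "sd":
        col = fit.design.X[:, names.index(f"L.{scenario.shocked}")]
        shock = scenario.size * float(np.std(col, ddof=1))
    else:
        shock = scenario.size

    n_total = scenario.burn_in + scenario.horizon
    shock_abs = scenario.burn_in + scenario.shock_time
    sigma = np.sqrt(fit.ols.sigma2)

    keep = draws[:, i_th0] < 0
    n_div = int((~keep).sum())
    draws = draws[keep]
    n_kept = draws.shape[0]
    if n_kept == 0:
        raise ValueError("all parameter draws were divergent (th0 >= 0)")

    # per-draw steady state at the baseline regressor levels
    th0 = draws[:, i_th0]
    const = draws[:, i_const] if i_const is not None else 0.0
    level_sum = np.zeros(n_kept)
    for r in spec.regressors:
        level_sum += draws[:, names.index(f"L.{r}")] * xbar[r]
    y0 = -(const + level_sum) / th0

    paths = np.empty((n_kept, n_total))
    y_prev = y0.copy()
    dy_hist = [np.zeros(n_kept) for _ in range(max(spec.p - 1, 0))]

    for t in range(n_total):
        x_now = {
            r: xbar[r]
            + (
                shock
                if r == scenario.shocked
                and (t >= shock_abs if scenario.permanent else t == shock_abs)
                else 0.0
            )
            for r in spec.regressors
        }
        x_prev_t = {
            r: xbar[r]
            + (
                shock
                if r == scenario.shocked
                and (t - 1 >= shock_abs if scenario.permanent else t - 1 == shock_abs)
                else 0.0
            )
            for r in spec.regressors
        }
        dy = const + th0 * y_prev
        for r in spec.regressors:
            dy += draws[:, names.index(f"L.{r}")] * x_prev_t[r]
        for i in range(1, spec.p):
            dy += draws[:, names.index(f"LD{i}.{spec.dependent}")] * dy_hist[i - 1]
        for r in spec.regressors:
            for j in range(spec.q_for(r) + 1):
                nm = f"D.{r}" if j == 0 else f"L{j}D.{r}"
                dx = _dx_at(t - j, shock_abs, shock, scenario.permanent) if r == scenario.shocked else 0.0
                dy += draws[:, names.index(nm)] * dx
        if scenario.mode == "predicted":
            dy = dy + sigma * rng.standard_normal(n_kept)
        y_now = y_prev + dy
        paths[:, t] = y_now
        if dy_hist:
            dy_hist = [dy] + dy_hist[:-1]
        y_prev = y_now

    bands = summarize_bands(paths)
    return SimulationPaths(
        paths=paths,
        time=np.arange(n_total),
        shock_period=shock_abs,
        scenario=scenario,
        bands=bands,
        n_divergent=n_div,
        shock_log_units=shock,
    )


def _dx_at(t: int, shock_abs: int, shock: float, permanent: bool) -> float:
    """Change in the shocked regressor at period t (step shift at shock_abs)."""
    if permanent:
        return shock if t == shock_abs else 0.0
    # impulse: up at the shock period, back down the next
    if t == shock_abs:
        return shock
    if t == shock_abs + 1:
        return -shock
    return 0.0
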