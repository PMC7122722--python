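"""Common lag-order selection for the ARDL stage via VAR information criteria.

All candidate lag orders 0..max_lag are scored on one common estimation
sample (the first ``max_lag`` rows are held out) so their likelihoods are
comparable.  Reported criteria follow the usual per-observation
conventions:

    AIC = -2 LogL/T + 2 n/T        SBC = -2 LogL/T + n ln(T)/T
    HQ  = -2 LogL/T + 2 n ln(ln T)/T
    FPE = ((T + pk + 1)/(T - pk - 1))^k det(Sigma)

with n the total parameter count k(pk+1), plus the sequential modified
likelihood-ratio test with small-sample correction.  The Schwarz criterion
(SBC) is the operative default for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TimeSeriesDataset

__all__ = ["LagOrderTable", "var_lag_selection"]


@dataclass
class LagOrderTable:
    """Per-lag criteria with per-criterion selections."""

    table: pd.DataFrame  # index: lag; columns: LogL, LR, LR_pvalue, FPE, AIC, SBC, HQ
    selected: dict[str, int]  # criterion -> chosen lag
    chosen: int  # the operative (SBC) choice
    estimation_sample: tuple[str, str]

    def __str__(self) -> str:  # Table-2-shaped text grid
        t = self.table.copy()
        for crit, lag in self.selected.items():
            if crit in t.columns:
                t[crit] = t[crit].map(lambda v: f"{v:.4g}")
                t.loc[lag, crit] = t.loc[lag, crit] + "*"
        return t.to_string()


def var_lag_selection(
    ds: TimeSeriesDataset,
    max_lag: int = 3,
    variables: list[str] | None = None,
    lr_level: float = 0.05,
) -> LagOrderTable:
    """Score VAR(0..max_lag) on a common sample and select per criterion."""
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    variables = variables or ds.variables
    Y = ds.frame[variables].to_numpy(dtype=float)
    T_full, k = Y.shape
    T = T_full - max_lag  # common estimation sample
    if T_full <= k * max_lag + 10:
        raise ValueError(f"n_obs={T_full} too small for k={k}, max_lag={max_lag}")

    Ycommon = Y  # rows are aligned by always dropping the first max_lag obs
    rows = {}
    ln_dets = {}
    for p in range(max_lag + 1):
        # common sample: regress rows max_lag..T_full-1 regardless of p
        sample_rows = np.arange(max_lag, T_full)
        Z = [np.ones(sample_rows.size)]
        for lag in range(1, p + 1):
            Z.append(Ycommon[sample_rows - lag])
        Z = np.column_stack(Z)
        target = Ycommon[sample_rows]
        coef, _, rank, _ = np.linalg.lstsq(Z, target, rcond=None)
        if rank < Z.shape[1]:
            raise ValueError(f"rank-deficient VAR design at lag {p}")
        resid = target - Z @ coef
        sigma = resid.T @ resid / T
        sign, ln_det = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise ValueError(f"singular residual covariance at lag {p}")
        ln_dets[p] = ln_det
        logl = -0.5 * T * (k * np.log(2 * np.pi) + ln_det + k)
        n_par = k * (k * p + 1)
        aic = -2 * logl / T + 2 * n_par / T
        sbc = -2 * logl / T + n_par * np.log(T) / T
        hq = -2 * logl / T + 2 * n_par * np.log(np.log(T)) / T
        fpe = ((T + p * k + 1) / (T - p * k - 1)) ** k * np.exp(ln_det)
        rows[p] = dict(LogL=logl, FPE=fpe, AIC=aic, SBC=sbc, HQ=hq)

    # sequential modified LR tests: H0 lag p-1 vs H1 lag p
    for p in range(max_lag + 1):
        if p == 0:
            rows[p]["LR"] = np.nan
            rows[p]["LR_pvalue"] = np.nan
        else:
            c = k * p + 1  # parameters per equation under the alternative
            lr = (T - c) * (ln_dets[p - 1] - ln_dets[p])
            rows[p]["LR"] = lr
            rows[p]["LR_pvalue"] = float(stats.chi2.sf(lr, k * k))

    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table[["LogL", "LR", "LR_pvalue", "FPE", "AIC", "SBC", "HQ"]]
    table.index.name = "lag"

    selected = {crit: int(table[crit].idxmin()) for crit in ("FPE", "AIC", "SBC", "HQ")}
    # LR: largest lag whose sequential test rejects at lr_level
    rejecting = [p for p in range(1, max_lag + 1) if table.loc[p, "LR_pvalue"] < lr_level]
    selected["LR"] = max(rejecting) if rejecting else 0

    start = str(ds.time_index[max_lag])
    end = str(ds.time_index[-1])
    return LagOrderTable(
        table=table,
        selected=selected,
        chosen=selected["SBC"],
        estimation_sample=(start, end),
    )
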