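"""Embedded critical-value tables used by the testing stages.

Three tables live here so the whole pipeline runs offline:

* Dickey-Fuller critical values via the MacKinnon (2010) response-surface
  coefficients ``cv(T) = b0 + b1/T + b2/T^2 + b3/T^3`` for the three
  deterministic specifications (none / constant / constant+trend).
* Pesaran-Shin-Smith (2001) bounds-test critical values, Case III
  (unrestricted intercept, no trend), k = 1..10 level regressors.
* 5% critical offsets for the CUSUM-of-squares stability test: two-sided
  crossing bounds for the maximum deviation of the cumulative squared
  recursive-residual share from its expectation, computed once by Monte
  Carlo (1e5 replicates per sample size, synthetic table) and linearly
  interpolated in the effective sample size T-k.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Dickey-Fuller (MacKinnon 2010 response surfaces), single series (N=1)
# rows: 1%, 5%, 10%; columns: b0..b3
_DF_TAU = {
    "n": np.array(
        [
            [-2.56574, -2.2358, -3.627, 0.0],
            [-1.94100, -0.2686, -3.365, 31.223],
            [-1.61682, 0.2656, -2.714, 25.364],
        ]
    ),
    "c": np.array(
        [
            [-3.43035, -6.5393, -16.786, -79.433],
            [-2.86154, -2.8903, -4.234, -40.040],
            [-2.56677, -1.5384, -2.809, 0.0],
        ]
    ),
    "ct": np.array(
        [
            [-3.95877, -9.0531, -28.428, -134.155],
            [-3.41049, -4.3904, -9.036, -45.374],
            [-3.12705, -2.5856, -3.925, -22.380],
        ]
    ),
}

DF_LEVELS = (0.01, 0.05, 0.10)


def dickey_fuller_crit(nobs: int, deterministic: str) -> dict[float, float]:
    """Finite-sample Dickey-Fuller critical values at 1/5/10%.

    ``deterministic`` is one of ``"n"`` (no deterministics), ``"c"``
    (constant) or ``"ct"`` (constant and linear trend).
    """
    if deterministic not in _DF_TAU:
        raise ValueError(f"unknown deterministic spec {deterministic!r}; use n/c/ct")
    if nobs < 10:
        raise ValueError("need at least 10 observations for critical values")
    T = float(nobs)
    powers = np.array([1.0, 1.0 / T, 1.0 / T**2, 1.0 / T**3])
    cvs = _DF_TAU[deterministic] @ powers
    return dict(zip(DF_LEVELS, cvs.tolist()))


# ---------------------------------------------------------------------------
# Pesaran, Shin & Smith (2001), Table CI(iii): unrestricted intercept,
# no trend.  {k: {level: (I0, I1)}}
_PSS_CASE_III = {
    1: {0.10: (4.04, 4.78), 0.05: (4.94, 5.73), 0.025: (5.77, 6.68), 0.01: (6.84, 7.84)},
    2: {0.10: (3.17, 4.14), 0.05: (3.79, 4.85), 0.025: (4.41, 5.52), 0.01: (5.15, 6.36)},
    3: {0.10: (2.72, 3.77), 0.05: (3.23, 4.35), 0.025: (3.69, 4.89), 0.01: (4.29, 5.61)},
    4: {0.10: (2.45, 3.52), 0.05: (2.86, 4.01), 0.025: (3.25, 4.49), 0.01: (3.74, 5.06)},
    5: {0.10: (2.26, 3.35), 0.05: (2.62, 3.79), 0.025: (2.96, 4.18), 0.01: (3.41, 4.68)},
    6: {0.10: (2.12, 3.23), 0.05: (2.45, 3.61), 0.025: (2.75, 3.99), 0.01: (3.15, 4.43)},
    7: {0.10: (2.03, 3.13), 0.05: (2.32, 3.50), 0.025: (2.60, 3.84), 0.01: (2.96, 4.26)},
    8: {0.10: (1.95, 3.06), 0.05: (2.22, 3.39), 0.025: (2.48, 3.70), 0.01: (2.79, 4.10)},
    9: {0.10: (1.88, 2.99), 0.05: (2.14, 3.30), 0.025: (2.37, 3.60), 0.01: (2.65, 3.97)},
    10: {0.10: (1.83, 2.94), 0.05: (2.06, 3.24), 0.025: (2.28, 3.50), 0.01: (2.54, 3.86)},
}

BOUNDS_LEVELS = (0.10, 0.05, 0.025, 0.01)


def bounds_crit(k: int, level: float, case: str = "unrestricted_intercept") -> tuple[float, float]:
    """Asymptotic bounds critical values ``(cv_I0, cv_I1)``.

    Only the unrestricted-intercept / no-trend case is embedded (the case
    the fire-climate models use).  ``k`` counts the level regressors
    excluding the lagged dependent variable.
    """
    if case != "unrestricted_intercept":
        raise ValueError(f"unsupported bounds case {case!r}")
    if k not in _PSS_CASE_III:
        raise ValueError(f"k must be in 1..10, got {k}")
    if level not in _PSS_CASE_III[k]:
        raise ValueError(f"level must be one of {BOUNDS_LEVELS}, got {level}")
    return _PSS_CASE_III[k][level]


# ---------------------------------------------------------------------------
# CUSUM-of-squares 5% two-sided crossing offsets c0 by effective sample
# size m = T - k.  Synthetic table: simulated under the null (iid normal
# recursive residuals), 1e5 replicates per m, seed 20260922.
_CUSUMSQ_M = np.array([10, 15, 20, 25, 30, 40, 50, 60, 80, 100, 150, 200, 300])
_CUSUMSQ_C0 = np.array(
    [
        0.47427, 0.41070, 0.36705, 0.33553, 0.30942, 0.27462, 0.24810,
        0.22939, 0.19976, 0.18051, 0.14926, 0.13042, 0.10710,
    ]
)


def cusumsq_crit(m: int) -> float:
    """5% critical offset for the CUSUMSQ path at effective size ``m = T - k``.

    Linear interpolation within the tabulated range; beyond 300 the offset
    is extrapolated with the 1/sqrt(m) large-sample shape.
    """
    if m < 2:
        raise ValueError("need at least 2 recursive residuals")
    if m <= _CUSUMSQ_M[-1]:
        return float(np.interp(m, _CUSUMSQ_M, _CUSUMSQ_C0))
    return float(_CUSUMSQ_C0[-1] * np.sqrt(_CUSUMSQ_M[-1] / m))
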