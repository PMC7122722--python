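# Methods

## Model

The analysis treats the log of monthly grassland area burned, y_t, as tied
to the logs of seven climate/emission drivers x_t = (cem, rel_humidity,
t_min, t_max, precip, sunlight, wind) through a single cointegrating
relation estimated in conditional error-correction form:

    Δy_t = α₀ + θ₀ y_{t−1} + Σ_k θ_k x_{k,t−1}
         + Σ_{i=1}^{p−1} α_i Δy_{t−i} + Σ_k Σ_{j=0}^{q_k} β_{k,j} Δx_{k,t−j} + ε_t

estimated by OLS. Long-run elasticities are κ_k = −θ_k/θ₀; θ₀ is the
error-correction coefficient ECM(−1), the fraction of a disequilibrium
closed per month (θ₀ ∈ (−2, 0) for a converging model, θ₀ ≥ 0 flagged as
"no error correction"). Standard errors for κ_k use the delta method on
the (θ₀, θ_k) block of s²(X′X)⁻¹; the delta method was preferred to a
Bewley-transform regression because it is closed-form and directly
checkable against simulation (CI coverage is itself a tested property).

Difference-lag convention: the Δx blocks run j = 0..q_k and the Δy lags
run i = 1..p−1. With the default p = 1 and q_k = 1 the estimation sample
loses two leading rows (one to differencing, one to the lagged
difference). An order of q_k = 0 admits only the contemporaneous Δx_k.

### Inference stages

* **Unit roots.** ADF with Schwarz-criterion lag choice over a common
  sample (Schwert-rule maximum), and Phillips–Perron with a Bartlett
  long-run variance at bandwidth ⌊4(n/100)^{2/9}⌋. Critical values come
  from the MacKinnon (2010) response surfaces, embedded for the three
  deterministic specifications. Defaults: constant+trend at the level,
  constant only for differences; decisions at 5%. A variable needing two
  differences (I(2)) halts the pipeline, since bounds critical values are
  only valid for mixtures of I(0) and I(1) regressors.
* **Lag order.** VAR(0..max_lag) scored on one common sample; AIC/SBC/HQ
  as −2·LogL/T + penalty·n_par/T, FPE with the usual finite-sample
  multiplier, and the sequential modified LR test with small-sample
  correction (T − parameters per equation). SBC is the operative choice.
* **Bounds test.** Wald F that all k+1 lagged-level coefficients
  (including the lagged dependent level) are jointly zero, against the
  embedded Pesaran–Shin–Smith Table CI(iii) bounds (unrestricted
  intercept, no trend, k = 1..10). F above the I(1) bound ⇒ cointegrated;
  below the I(0) bound ⇒ no level relationship; between ⇒ inconclusive.
* **Shock simulation.** Coefficient draws b⁽ˢ⁾ ~ MVN(b̂, V̂) (SVD
  factorization). Regressors are pinned at sample means; each draw's
  recursion starts at its own steady state, a permanent step of the chosen
  size (default +1 SD of the shocked regressor's log level) is applied at
  the shock time, and the response path is recorded over
  burn-in + horizon periods (defaults 20 + 20, shock at 10). Draws with
  θ₀ ≥ 0 cannot converge; they are excluded from the bands and their count
  is always reported. The default expected-values mode injects no residual
  noise, which makes the long-run algebra exact: each path converges
  geometrically at rate (1 + θ₀) to a new equilibrium displaced by
  −θ_shock/θ₀ × shock. Predicted-values mode adds N(0, s²) noise per
  period. Band levels 75/90/95% are empirical central quantiles per
  period and are nested by construction.
* **Diagnostics.** ARCH-LM (T·R² on lagged squared residuals),
  Breusch–Godfrey ((T−m)·R² with zero-padded lagged residuals), Ramsey
  RESET (F on powers 2–3 of rescaled fitted values), Jarque–Bera, and
  Brown–Durbin–Evans CUSUM/CUSUMSQ on standardized one-step-ahead
  recursive residuals. CUSUM bounds are the 5% straight lines
  ±0.948[√(T−k) + 2(r−k)/√(T−k)]. CUSUMSQ offsets are a table of exact
  two-sided 5% crossing bounds simulated under the null (10⁵ replicates
  per effective sample size, fixed seed; a synthetic table, linearly
  interpolated in T−k and extended beyond T−k = 300 with the 1/√m
  large-sample shape). Diagnostic lag counts default to 1. Seasonal
  correlations pool the FMA/MJJ/ASO month triplets and report Pearson r
  with two-sided t-based p-values; they use whatever scale the dataset is
  on (raw by default in the pipeline, before the log stage).

## Synthetic data

The generator emulates the statistical skeleton the analysis assumes:

* regressors are independent driftless random walks in logs (innovation SD
  0.05 log units/month — a realistic month-to-month variation for log
  climate series), optionally stationary AR(1);
* the response follows the ECM recursion with adjustment speed
  ρ = −0.611 and elasticities mirroring the published fire–climate
  magnitudes (wind 20.81, t_max 8.651, sunlight 4.481, cem 2.616, precip
  1.421, rel_humidity 1.102, t_min 1.026), started at equilibrium;
* short-run dynamics default to one lag of each Δx with coefficients
  0.1·κ_k;
* the ECM innovation SD defaults to 0.02 log units, the residual scale
  implied by the published sum of squared residuals (≈0.06 over ≈200
  monthly observations);
* options: a multiplicative month-of-year seasonal lift of the response
  (Apr/May/Sep peaks, zero in winter; off by default so estimation checks
  are exact), and a midsample rescaling of selected elasticities for
  stability-test power studies.

What the generator does **not** emulate: bounded physical supports
(humidity ≤ 100%), zero-inflation of burned area (handled in the I/O layer
by the +1-before-log convention instead), cross-correlated climate
drivers, and measurement error. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Numerical choices

* All regressions go through one QR-based least-squares core; covariance
  s² uses the n − n_par denominator; rank deficiency is an error naming
  the dependent columns.
* Fitted-value powers in RESET are computed on fitted values rescaled by
  their maximum absolute value to keep the augmented design conditioned.
* The bounds F uses the Wald form b′[RVR′]⁻¹b/q; tests verify equality
  with the restricted-vs-unrestricted SSR form to 1e−8.
* Recursive residuals update X′X by rank-one accumulation with a fresh
  solve per step; a singular update raises at the offending step.
* Seeds: every stochastic component takes an explicit seed; the pipeline
  fans a single config seed out to per-stage seeds by a fixed offset
  scheme, so one integer reproduces a whole run byte-for-byte.

## Design notes and known limitations

* **Stability testing.** CUSUM and CUSUMSQ answer different alternatives.
  A large, abrupt coefficient break (e.g. doubling a dominant elasticity
  of magnitude ≈20) produces a variance-type disturbance: a few enormous
  transition residuals inflate the CUSUM normalizing SD and the CUSUM path
  rarely leaves its bounds, while CUSUMSQ flags essentially every
  replicate. A moderate single-coefficient break (doubling the
  unit-magnitude t_min elasticity in the wind/t_max/t_min system) yields a
  sustained signed drift that CUSUM detects in ≈95% of replicates at ≈4%
  false-alarm rate. The stability power studies therefore use the
  three-driver system with the t_min break; both statistics are always
  reported. On the full eight-variable I(1) design, CUSUM's finite-sample
  false-alarm rate is inflated (≈20%) by the near-collinearity of the
  level columns — the recursive residuals themselves were verified against
  an independent recursive-least-squares implementation, so this is a
  property of the statistic, not of the code.
* **Bounds-test size.** The "no cointegration" null is a response evolving
  independently of the regressors (short-run spillovers zeroed); with
  spillovers present the response is near-cointegrated with the drivers by
  construction and rejection is the correct behavior.
* **Simulation horizon.** The long-run limit-law check lengthens the
  horizon (60 periods, shock at 5) so the geometric recursion converges
  well below Monte-Carlo resolution; at the default 20-period display
  horizon the remaining disequilibrium after 10 post-shock periods is
  ≈(1+ρ)^10 of the initial gap and still visible at high draw counts.
* **Problem sizes.** Replicate counts (200 for recovery/size/power, 1000
  for ADF size, 5000 simulation draws) match the study-scale conditions
  and keep any full verification run in the tens of seconds on one CPU.
* The monthly design keeps winter months (no fires) via the +1 log offset
  on area burned and emissions; an alternative mode drops the non-fire
  season months instead. No imputation is performed: rows with missing
  values are dropped and logged.
* Per-regressor exhaustive lag search (2⁸ order combinations) is out of
  scope; orders are set by the spec string or the VAR-level criteria.
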