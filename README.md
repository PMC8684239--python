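# parsurvsim

Monte-Carlo evaluation of **parametric survival extrapolation under limited
data** — small samples and short follow-up — for the quantities that drive
health-technology-assessment (HTA) decision models.

When a trial reports time-to-event data, decision modellers fit a parametric
survival family, extrapolate it to a lifetime horizon, and read off median
survival, landmark survival, the "lifetime" horizon and restricted mean
survival time (life-years). This package quantifies how badly that procedure
can go wrong when the trial is small or immature, even in the easiest
possible world: data generated from a known exponential distribution with
the candidate set containing the truth.

## Who it is for

Biostatisticians and health economists studying extrapolation methodology;
anyone who needs a reproducible simulation bench for censored parametric
fitting, information-criterion model selection, and simulation performance
measures (coverage, error, MCSE) in the ADEMP style.

## The simulation in brief

**Data.** A population of k = 50,000 individuals with staggered trial
enrollment t₁ₖ ~ Uniform(1, T₁) days and event times t₂ₖ ~ Exponential(λ₁₂)
days from enrollment. The primary scenario uses T₁ = 270 (9 months) and
λ₁₂ = 0.0025/day, so median survival is −ln(0.5)/λ ≈ 277 days; three
companion scenarios vary accrual (30 months) and rate (0.00075/day).
Samples of n ∈ {30, 60, 90, 120, 250, 500} are drawn per repetition and
administratively censored at the calendar time when each decile
pₑ ∈ {10%, …, 100%} of the sample has had its event; the clock then resets
to enrollment for analysis.

**Methods under study.** Six families fitted by right-censored maximum
likelihood — exponential, Weibull, log-normal, log-logistic, generalized
gamma (Prentice μ, σ, Q) and Gompertz — with the likelihood

&nbsp;&nbsp;ℓ(θ) = Σ_events log f(tᵢ; θ) + Σ_censored log S(tᵢ; θ),

implausible fits removed by prespecified filters (nonconvergence,
non-descending survival, a 95% CI wider than 0.80 in survival probability at
the first event time, infinite estimators, median beyond the population's
largest event time), and the best fit chosen by AIC = −2ℓ + 2k or
BIC = −2ℓ + k ln n (AICc/BICc also available).

**Estimands.** median; S(365); the time horizon TH where S(TH) = 0.01; RMST
∫₀ᵀ S(t) dt at the fixed population horizon TH_pop and at the sample's own
estimated horizon TH_i. 95% intervals come from B = 1000 multivariate-normal
parameter draws on the unconstrained scale.

**Performance.** Proportion selecting the true family; coverage; MAE, MAPE,
RMSE; probability of >20% error — each with Monte-Carlo standard errors.

## Worked example

Fitting all six families to one simulated trial (120 patients, analyzed
when 50% have had events — `python analysis/02_fit_families.py`):

```
dataset: 120 subjects accrued, 60 events, censored on study day 398
     family      loglik        aic        bic  plausible  median_days
exponential -416.081615 834.163231 836.950722       True        262.0
    weibull -414.353919 832.707838 838.282821       True        269.8
  lognormal -413.788708 831.577416 837.152400       True        277.2
loglogistic -413.730634 831.461269 837.036252       True        267.7
   gengamma -413.610274 833.220549 841.583024       True        272.0
   gompertz -413.748790 831.497580 837.072563      False        266.7
best by AIC: loglogistic (true family chosen: False)
best by BIC: exponential (true family chosen: True)
```

The data are truly exponential (median 277 days), yet AIC prefers the
log-logistic — its two parameters buy a likelihood gain worth more than
AIC's penalty — while BIC's stiffer ln(n) penalty recovers the truth. The
Gompertz fit converged but is filtered out: its survival curve plateaus
above 1%, so its lifetime horizon is infinite. Run at scale
(`analysis/03_identification_rates.py`, `analysis/04_error_and_coverage.py`)
this becomes: BIC selects the exponential in ~90% of repetitions on average
(~98% at n=500 with complete follow-up) against ~68% for AIC; and with the
true family *given*, median-survival MAPE still ranges from ~44% (n=30, 10%
of events) to ~3% (n=500, complete follow-up), with ~70% of small immature
trials missing the truth by more than 20%.

## Command line

```bash
parsurvsim simulate --scenario 1 --n-sim 10 --out datasets.csv
parsurvsim run --scenario 1 --n-sim 100 --seed 7 --criteria aic,bic \
    --out runs/s1 --workers 4
parsurvsim run --scenario 1 --n-sim 500 --out runs/s1 --resume
parsurvsim summarize --out runs/s1 --criterion bic --estimand median
```

Runs are deterministic given `--seed` (independent per-repetition
substreams), resumable, and independent of `--workers`.

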