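# htnscreen

Cost-effectiveness modelling of population screening for hypertension in the
prevention of cardiovascular disease (CVD), for health-economic analysts and
epidemiologists evaluating screening policy in resource-limited settings.

The package implements a decision tree feeding a ten-state Markov cohort
model with one-year cycles. Adults enter as healthy, unaware hypertensive
(detectable only by screening) or symptom-aware hypertensive (a
treatment-uptake fraction of whom is on therapy). Hypertensives face annual
risks of non-fatal and fatal CVD from a log-linear risk equation,

    rate(a, s) = exp(c + beta_age * a + beta_sex * s),    s = 1 for men,

with separate intercepts for non-fatal (c = −9.54) and fatal (c = −10.67)
events and shared coefficients (beta_age = 0.07, beta_sex = 0.55), converted
to annual probabilities by p = 1 − exp(−rate). CVD is a composite of 78%
stroke and 22% myocardial infarction. Antihypertensive treatment scales
event risk on the rate scale with relative risks RR = 0.72 (acute CVD) and
RR = 0.82 (CVD death). Survivors of an acute event move to stable CVD and
may recur; background non-CVD mortality comes from a life table net of its
CVD share. Screening strategies (one-off, annual, biannual, biannual
switching to annual at a given age, each optionally combined with +20%
treatment coverage) diagnose the unaware pool at scheduled cycles.

Costs (screening rounds, annual hypertension treatment, first-year acute CVD
care, stable CVD follow-up; international dollars at purchasing-power
parity) and quality-adjusted life years (QALYs, utility-weighted state
occupancy) are discounted (3% costs, 0% QALYs by default) and reported per
1,000 entrants. Strategies are compared with no screening through
incremental cost-effectiveness ratios, ICER = ΔC/ΔE, with dominance
handling, against a willingness-to-pay threshold of three times GDP per
capita. Parameter uncertainty is propagated by probabilistic sensitivity
analysis (gamma costs, beta utilities/probabilities, lognormal relative
risks, Cholesky-correlated risk-coefficient draws) summarised as
cost-effectiveness acceptability curves, plus a univariate tornado
analysis. A synthetic-data module supplies the survey-derived inputs (life
table, age/sex prevalence) that are not publicly deposited, and an
individual-level microsimulation that serves as an independent oracle for
the cohort engine.

## Worked example

```python
import htnscreen as h

params = h.synth_parameter_set()          # published point estimates +
                                          # synthetic life table/prevalence
threshold = h.wtp_threshold(params.econ.gdp_per_capita,
                            params.econ.wtp_multiplier)   # 15882.0

scenarios = h.standard_scenarios("male", 55, "ten_year")
results = [h.accrue(h.run_cohort(s, params), params.econ) for s in scenarios]
print(h.compare_strategies(results, threshold).round(3).to_string(index=False))
```

```
                      strategy  total_cost  total_qaly  incr_cost  incr_qaly icer_or_dominance cost_effective
         male/55/ten_year/none  119004.836    8191.787        NaN        NaN                              NaN
      male/55/ten_year/one_off  174342.108    8193.697  55337.272      1.910            28,975          False
       male/55/ten_year/annual  215414.904    8194.066  96410.068      2.279            42,305          False
     male/55/ten_year/biannual  197695.720    8194.016  78690.883      2.228            35,312          False
  male/55/ten_year/annual+T1.2  232555.908    8194.710 113551.072      2.923            38,853          False
male/55/ten_year/biannual+T1.2  214563.751    8194.649  95558.915      2.862            33,389          False
```

Each row is one screening strategy for men starting at age 55 over a
ten-year horizon: discounted cost (Int$) and QALYs per 1,000 entrants, the
increments against no screening, the ICER (Int$ per QALY gained, or a
dominance label), and whether the strategy is cost-effective at the 3×GDP
threshold of Int$ 15,882/QALY. Here one-off screening gains 1.91 QALYs per
1,000 men for Int$ 55,337, an ICER of Int$ 28,975/QALY — above the
threshold under the synthetic inputs; lifetime horizons and older cohorts
give substantially lower ratios (see `horizon="lifetime"`).

The same analyses are available from a shell:

```sh
htnscreen run --sex male --start-age 55 --out-dir out/
htnscreen psa --n-draws 5000 --seed 1 --out-dir out/
htnscreen sa  --strategy biannual --out-dir out/
htnscreen fixtures --out-dir fixtures/
```

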