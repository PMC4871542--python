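# Methods

## Model structure

The model couples a decision tree at entry with a Markov cohort model run
in one-year cycles. Ten states are tracked: healthy; hypertensive
undiagnosed; hypertensive diagnosed-untreated; hypertensive treated; acute
CVD and stable CVD, each carrying a treated/untreated flag; and two
absorbing death states (CVD and non-CVD). The decision tree allocates the
entry cohort from age- and sex-specific prevalence: the symptom-aware pool
is diagnosed at entry and a treatment-uptake fraction of it (62% of women,
48% of men; multiplied by the coverage factor in the "+20%" scenarios) is
on therapy; the screen-detectable pool starts undiagnosed; everyone else is
healthy and can become hypertensive at a constant annual incidence (0.0065
women, 0.0164 men), entering the undiagnosed pool.

Within each cycle events are ordered: screening (at scheduled cycles),
transitions, accrual. A screening round diagnoses the entire undiagnosed
pool present at that cycle — the two-visit confirmation of a real campaign
is collapsed into one model event, with incomplete attendance already
embedded in the detected/undetected prevalence split — and moves the uptake
share onto treatment. Healthy attendees incur the screening cost without
changing state. Diagnosed-untreated people are not re-screened: they are
already aware.

Hypertensive states face annual probabilities of non-fatal CVD (to acute),
fatal CVD (to CVD death) and non-CVD death. From acute CVD, patients die of
the acute event (annual probability 0.008 untreated) or of background
causes, suffer a recurrent event (remaining acute), or stabilise. From
stable CVD, they recur to acute, die of CVD or background causes, or stay.
Recurrence uses the same age/sex probabilities as first events
(history-independence): no data support an elevated recurrent risk, so the
model is conservative about screening's benefit on recurrences. Treatment
status persists through the CVD states, so relative risks — and treatment
costs — keep applying after an event.

## Transition probabilities

CVD event rates come from a log-linear equation in age and sex,
`rate = exp(c + 0.07*age + 0.55*male)`, with intercepts −9.54 (non-fatal)
and −10.67 (fatal). The log-rate reading was chosen over a logistic one
because the printed coefficients then imply plausible annual probabilities
(≈0.6%/year non-fatal for a 55-year-old man); a logistic alternative is
selectable via `RiskCoefficients.functional_form`. Other predictors (blood
pressure, cholesterol, smoking) are grand-mean-centred into the intercept,
so only age and sex appear at runtime. Rates convert to probabilities under
a constant hazard, `p = 1 − exp(−rate·t)`, and back by
`rate = −ln(1−p)/t`; the two are mutual inverses to better than 1e−12 over
the probabilities the model uses.

Treatment applies relative risks on the rate scale,
`p_treated = 1 − (1−p)^RR`, which agrees with naive multiplication to
O(p²) at small p but remains a valid probability near 1. The CVD-death RR
(0.82) also applies to the acute-to-fatal transition under treatment by
default (`epi.rr_death_on_acute`), on the reading that a treated patient's
acute case fatality benefits like other CVD mortality; a switch disables
it. An optional age-dependent RR mapping,
`rr(age) = rr_base * exp(slope*(age − anchor))` with anchor 55 and slope
0.005/year by default, leaves the base-case RR unchanged at the anchor age
and weakens protection at older ages, for scenario analysis.

Background mortality is the life-table crude probability times
`1 − cvd_death_fraction`, so CVD deaths enter only through the model's own
fatal transitions and are never double-counted. The CVD share of crude
mortality is not published for this setting; the default 0.25 is a
synthetic, configurable placeholder.

## Economics

Four cost components (Int$, PPP-converted at 7,546.6 VND/Int$, year 2013):
screening 6.05 per attendee-round; hypertension treatment 70.82 per treated
person-year, charged to every treated state including treated CVD states
(therapy persists, so its cost must too); acute CVD 3,723.24 per
person-year of acute-state occupancy (the first year after an event,
including recurrences); stable CVD 79.39 per person-year. Utilities:
healthy 0.93; hypertension 0.74 (men) / 0.71 (women), identical for
treated and untreated; acute CVD 0.67; stable CVD 0.72 / 0.71. An
alternative GBD-derived set (0.957 / 0.835 / 0.685 / 0.717) supports the
international-comparison analysis. Costs discount at 3%/year and QALYs at
0% by default, cycle 0 undiscounted. There is no half-cycle correction —
accrual uses the post-transition occupancy, so deaths earn nothing in the
cycle they occur. Totals are reported per 1,000 entrants; the ICER is
scale-invariant.

ICERs compare each strategy with no screening (not an efficiency
frontier). Sign logic: ratio ΔC/ΔE when ΔE ≠ 0; dominant when ΔC < 0 and
ΔE > 0; dominated when ΔC > 0 and ΔE < 0; undefined when ΔE = 0. The
cost-effectiveness flag uses net monetary benefit, `λ·ΔE − ΔC ≥ 0`, so a
ratio exactly at the threshold counts as cost-effective and the southwest
quadrant is handled correctly. The threshold defaults to
`wtp_multiplier × gdp_per_capita` (3 × 5,294 = 15,882 Int$/QALY); because
the source analysis quotes 15,883 — presumably from an unrounded GDP figure
— an explicit override is supported.

## Probabilistic sensitivity analysis

Families follow convention: gamma for costs, beta for utilities and
probabilities, lognormal for relative risks, all parameterised by method of
moments from (mean, SE). Lognormals are anchored at the median
(`mu = ln RR`), so the point estimate is the median rather than the mean of
the drawn RRs; mean-anchoring would shift mu by −sigma²/2 and is a
one-line change. Prevalence and uptake are held fixed, as in the source
analysis. Dispersion is not published; the default SE is 20% of the mean,
set per parameter in the `psa` block so the placeholder is never silent.

The four risk-equation coefficients are drawn jointly as `mean + L·z` with
L the Cholesky factor of their covariance. The covariance is not published
either; the default is diagonal with SEs expressed on the log-rate scale
the coefficients act on — 0.20 per intercept (the same SD convention as the
log relative risks), 0.004 for the age slope, 0.10 for the sex effect. A
"20% of coefficient magnitude" rule was rejected: an intercept's magnitude
depends on the arbitrary centring of the absorbed covariates, and SD ≈ 1.9
on a log scale makes most draws degenerate. Draws that still push a source
state's exit probabilities beyond 1 are renormalized by truncating the stay
probability, and the count of such events is reported on the trace and the
PSA sample (zero under the defaults). Degenerate coefficient draws with the
fatal intercept above the non-fatal one are reordered rather than rejected,
preserving determinism of the draw count.

All strategies within one draw share the same parameters (common random
parameters), reducing Monte Carlo variance of the increments. CEACs use the
net-monetary-benefit acceptance rule per draw. The default WTP grid spans 0
to 4×GDP in 101 points, which places the 3×GDP threshold exactly on the
grid. Because the risk equation is exponential in its coefficients, the PSA
mean of costs and QALYs sits slightly above/below the deterministic run (a
standard convexity effect, ~2–3% under the default dispersions); the PSA
machinery itself is unbiased, which the test suite verifies by drawing only
the blocks that enter the accrual linearly (costs, utilities), where the
deterministic increments are the exact expectation.

The univariate analysis perturbs, one at a time: the CVD transition
probability and each unit cost by ±25%; CVD utilities by −10%/−20%; QALY
discounting at 1%/3%; the GBD utility set; a national-survey prevalence
scenario (all prevalence pools ×1.25, reflecting a survey that measured
blood pressure on a single visit); and the age-dependent RR mapping. Rows
are ordered tornado style by |ICER − base| with alphabetical tie-breaking.

## Synthetic inputs and what they do not show

The survey tables and the national life table behind the original analysis
are not deposited, so the package generates stand-ins:

* **Life table** — Gompertz hazard `q(a) = 1 − exp(−alpha·e^(beta·a))`,
  with (alpha, beta) = (8.0e−5, 0.085) for men and (4.0e−5, 0.090) for
  women: annual death risk ≈0.9% (men) and 0.6% (women) at 55, near-certain
  death by 100, male excess mortality at every age. Chosen for demographic
  plausibility, not fitted to any real table.
* **Prevalence** — total hypertension prevalence logistic in age (midpoint
  50, steepness 0.15/year), spanning ≈8% at 35 to ≈38% (women) / 41% cap
  (men) at 64, inside the published 5–41% envelope. The screen-detectable
  share rises linearly from 56% to 72% of the total across 35–64, keeping
  the detectable pool inside 2.8–29.7% and the aware pool inside 2.2–15.3%;
  the two pools partition the total exactly. Ages outside 35–64 clamp to
  the nearest band (prevalence is only read at entry ages 35/45/55).

Point estimates (risk coefficients, RRs, costs, utilities, uptake,
incidence, the 0.008 acute fatality, discount rates, GDP and PPP) are the
published values verbatim. Everything is deterministic in the seed.

Consequently, passing tests show the *machinery* is correct — conservation,
oracle equivalence, orderings, distributional behaviour — and that the
published qualitative structure (ICERs falling with start age, male below
female, lifetime below ten-year) emerges from the published point estimates
under plausible demographic inputs. They do not certify the original
headline numbers, which depend on the unpublished age-specific tables. On
the synthetic inputs the ten-year grid reproduces the orderings strictly;
on the lifetime horizon the age ordering between 35 and 45 is flat to
within ~0.2% for some female scenarios.

The microsimulation oracle replays the same per-cycle probabilities by
categorical sampling per individual and re-implements accrual
independently; it never touches the cohort engine's matrix arithmetic. With
200,000 individuals the cohort occupancies agree within 3 binomial SEs per
cycle and state.

## Numerical choices and edge cases

* Mass conservation is enforced to 1e−9 every cycle; violations raise.
* Exit probabilities from any state exceeding 1 raise in deterministic
  runs; during PSA they trigger the stay-truncation renormalization above.
* `prob_to_rate` rejects p = 1; `rate_to_prob` rejects negative rates;
  conversions use expm1/log1p for precision at small probabilities.
* The Cholesky factorization validates symmetry and positive
  semi-definiteness (eigenvalue tolerance 1e−10 relative) and adds a 1e−12
  diagonal jitter only for exactly singular PSD inputs.
* Beta moment-matching rejects infeasible variances (se² ≥ mean(1−mean)).
* Lifetime horizons run to the end of the life table (age 100); residual
  alive mass simply stops accruing.
* The undiagnosed pool in non-screening arms stays undiagnosed
  (`symptomatic_diagnosis_prob` defaults to 0): entry awareness is already
  seeded from survey prevalence, and no symptom hazard thereafter is
  modelled. A nonzero value routes newly aware cases through the usual
  uptake split.
* The "+20% coverage" scenarios read the increase as relative (uptake
  ×1.2); an absolute mode (+20 points) is available via
  `Scenario.coverage_mode`.

## Limitations

No adherence gradient (treated means fully adherent); no individual
heterogeneity beyond age and sex; no recovery from CVD states; recurrence
risk not elevated over first-event risk; the CVD share of crude mortality
is a placeholder; costs are health-service perspective only, with a single
PPP conversion and no inflation adjustment; no EVPI computation. Problem
sizes used by the test and acceptance suites — 10–65 cycle cohorts, 200,000
microsimulated individuals, 500-draw scaled PSA, 1e5-draw moment checks —
were chosen so each check's Monte Carlo error is well below its tolerance.
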