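"""Per-cycle transition probabilities.

Annual CVD event rates come from a log-linear risk equation in age and sex
(separate intercepts for non-fatal and fatal events; male coded 1), fitted
with all other predictors grand-mean-centred into the intercept.  Rates and
probabilities are interconverted under a constant-hazard assumption,
p = 1 - exp(-r*t).  Antihypertensive treatment scales event risk on the
rate scale (power transform of the survival probability), which agrees with
direct probability multiplication to O(p^2) at small p but stays valid near
1.  Crude all-cause mortality from the life table is split so that only its
non-CVD share enters as background death; CVD mortality is generated solely
by the model's fatal-CVD transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import MALE, ParameterSet, RiskCoefficients

AGE_MIN, AGE_MAX = 18.0, 100.0


@dataclass(frozen=True)
class TransitionProbs:
    """Annual transition probabilities for one (age, sex, treated) stratum."""

    p_nonfatal_cvd: float
    p_fatal_cvd: float
    p_noncvd_death: float
    p_incidence: float
    p_acute_to_fatal: float


def annual_cvd_rate(age: float, sex: str, which: str,
                    coeffs: RiskCoefficients) -> float:
    """Annual CVD event rate for a hypertensive person of given age and sex.

    ``which`` selects the ``nonfatal`` or ``fatal`` intercept.  Under the
    default ``log_rate`` form the rate is exp(c + b_age*age + b_sex*male);
    the ``logistic`` alternative reads the linear predictor as a logit of an
    annual probability and converts back to a rate.
    """
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
    if which == "nonfatal":
        intercept = coeffs.intercept_nonfatal
    elif which == "fatal":
        intercept = coeffs.intercept_fatal
    else:
        raise ValueError(f"which must be 'nonfatal' or 'fatal', got {which!r}")
    male = 1.0 if sex == MALE else 0.0
    lp = intercept + coeffs.beta_age * age + coeffs.beta_sex * male
    if coeffs.functional_form == "logistic":
        p = 1.0 / (1.0 + math.exp(-lp))
        return prob_to_rate(p, 1.0)
    return math.exp(lp)


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Convert a constant hazard ``rate`` to an event probability over ``t`` years."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    return -math.expm1(-rate * t)


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Convert an event probability over ``t`` years to a constant hazard."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    return -math.log1p(-p) / t


def apply_treatment(p_untreated: float, rr: float) -> float:
    """Apply a relative risk on the rate scale: 1 - (1-p)^rr, clamped to [0, 1]."""
    if not 0.0 <= p_untreated <= 1.0:
        raise ValueError(f"probability {p_untreated} outside [0, 1]")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    if p_untreated == 1.0:
        return 1.0
    return min(max(-math.expm1(rr * math.log1p(-p_untreated)), 0.0), 1.0)


def composite(stroke_value: float, mi_value: float, w_stroke: float) -> float:
    """Stroke/MI-weighted composite of a quantity (RR, cost or utility)."""
    if not 0.0 <= w_stroke <= 1.0:
        raise ValueError(f"stroke weight {w_stroke} outside [0, 1]")
    return w_stroke * stroke_value + (1.0 - w_stroke) * mi_value


def split_mortality(q_crude: float, cvd_fraction: float) -> float:
    """Non-CVD share of crude mortality: q_crude * (1 - cvd_fraction).

    The CVD share never enters as background death — fatal CVD arises only
    from the model's own fatal transitions, avoiding double counting.
    """
    if not 0.0 <= q_crude <= 1.0:
        raise ValueError(f"q_crude {q_crude} outside [0, 1]")
    if not 0.0 <= cvd_fraction <= 1.0:
        raise ValueError(f"cvd_fraction {cvd_fraction} outside [0, 1]")
    return max(q_crude * (1.0 - cvd_fraction), 0.0)


def effective_rr(base_rr: float, age: float, params: ParameterSet) -> float:
    """Treatment RR at ``age``, applying the optional age-dependence mapping.

    With the mapping active, rr(age) = base * exp(slope * (age - anchor)),
    so the RR at the anchor age equals the base-case RR exactly.
    """
    dep = params.rr_age_dependence
    if not dep:
        return base_rr
    rr = base_rr * math.exp(dep["log_slope"] * (age - dep["anchor_age"]))
    return min(max(rr, 1e-6), 2.0)


def transition_probs(age: float, sex: str, treated: bool,
                     params: ParameterSet, check: bool = True) -> TransitionProbs:
    """Assemble all five annual probabilities for one (age, sex, treated) stratum.

    The treated flag applies the acute-CVD RR to the non-fatal transition and
    the CVD-death RR to the fatal transition; the acute-to-fatal probability
    is the constant 0.008 untreated and is RR-adjusted under treatment when
    ``epi.rr_death_on_acute`` is set (default).  With ``check`` (default),
    raises if the exit probabilities from the hypertension state exceed 1;
    the cohort engine disables the check for degenerate PSA draws, which it
    renormalizes itself.
    """
    epi = params.epi
    mult = epi.cvd_prob_multiplier
    p_nf = min(rate_to_prob(annual_cvd_rate(age, sex, "nonfatal", params.risk)) * mult, 1.0)
    p_f = min(rate_to_prob(annual_cvd_rate(age, sex, "fatal", params.risk)) * mult, 1.0)
    p_af = epi.p_acute_to_fatal
    if treated:
        p_nf = apply_treatment(p_nf, effective_rr(epi.rr_acute, age, params))
        rr_d = effective_rr(epi.rr_death, age, params)
        p_f = apply_treatment(p_f, rr_d)
        if epi.rr_death_on_acute:
            p_af = apply_treatment(p_af, rr_d)
    q_crude = params.life_table.q_crude(age, sex)
    p_noncvd = split_mortality(q_crude, epi.cvd_death_fraction)
    p_inc = epi.incidence_prob[sex]

    if check and p_nf + p_f + p_noncvd > 1.0 + 1e-12:
        raise ValueError(
            f"hypertension-state exit probabilities sum to "
            f"{p_nf + p_f + p_noncvd:.4f} > 1 at (age={age}, sex={sex}, "
            f"treated={treated})"
        )
    return TransitionProbs(
        p_nonfatal_cvd=p_nf,
        p_fatal_cvd=p_f,
        p_noncvd_death=p_noncvd,
        p_incidence=p_inc,
        p_acute_to_fatal=p_af,
    )
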