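"""Parameter uncertainty: PSA, CEAC curves and univariate sensitivity.

Probabilistic sensitivity analysis samples costs from gamma distributions,
utilities and probabilities from beta distributions, relative risks from
lognormals (anchored at the median, mu = ln RR), and the four risk-equation
coefficients jointly from a multivariate normal via the Cholesky factor of
their covariance.  All strategies within one Monte Carlo draw share the
same drawn parameters, which reduces the Monte Carlo variance of the
incremental results.  Cost-effectiveness acceptability curves use the
net-monetary-benefit acceptance rule, which avoids undefined per-draw
ratios when the QALY difference is near zero.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import run_cohort
from .economics import CEResult, accrue, icer, is_cost_effective, wtp_threshold
from .parameters import (
    FEMALE,
    MALE,
    DistributionSpec,
    ParameterSet,
    Scenario,
    apply_overrides,
)

#: key in the PSA block that triggers the joint (Cholesky) coefficient draw
RISK_BLOCK = "risk.coefficients"


# ---------------------------------------------------------------------------
# Distribution parameterization (method of moments)

def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError(f"gamma moments must be positive (mean={mean}, se={se})")
    shape = mean**2 / se**2
    scale = se**2 / mean
    return shape, scale


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and standard error."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError(f"beta se must be positive, got {se}")
    if se**2 >= mean * (1.0 - mean):
        raise ValueError(
            f"beta variance {se**2:.4g} infeasible: must be < mean(1-mean) "
            f"= {mean * (1 - mean):.4g}"
        )
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def lognormal_from_rr(rr_mean: float, se_log: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) for a relative risk, anchored at the median.

    mu = ln(rr) so the drawn RR has median equal to the point estimate;
    sigma is the SD of log RR.
    """
    if rr_mean <= 0:
        raise ValueError(f"relative risk must be positive, got {rr_mean}")
    return math.log(rr_mean), se_log


def cholesky_factor(cov: np.ndarray) -> np.ndarray:
    """Lower-triangular L with L @ L.T = cov; errors on non-PSD input."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    eigs = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eigs.min() < -1e-10 * max(abs(eigs.max()), 1.0):
        raise ValueError(f"covariance is not positive semi-definite (min eig {eigs.min():.3g})")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # PSD but singular: tiny diagonal jitter keeps the factor exact to ~1e-12
        jitter = 1e-12 * max(np.trace(cov), 1.0)
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))


# ---------------------------------------------------------------------------
# Default specs and drawing

def default_psa_specs(params: ParameterSet,
                      rel_se: float = 0.20) -> dict[str, DistributionSpec]:
    """Table-style PSA block: gamma for costs, beta for utilities and
    probabilities, lognormal for RRs, Cholesky for the risk coefficients.

    Dispersion defaults to ``rel_se`` x mean (SD of log RR = ``rel_se`` for
    lognormals); prevalence and uptake stay fixed.
    """
    e, c = params.epi, params.econ
    specs: dict[str, DistributionSpec] = {}
    for name, mean in (
        (f"epi.incidence_prob.{FEMALE}", e.incidence_prob[FEMALE]),
        (f"epi.incidence_prob.{MALE}", e.incidence_prob[MALE]),
        ("epi.p_acute_to_fatal", e.p_acute_to_fatal),
    ):
        specs[name] = DistributionSpec("beta", mean, rel_se * mean)
    for name, mean in (
        ("econ.cost_screen_round", c.cost_screen_round),
        ("econ.cost_htn_treat_year", c.cost_htn_treat_year),
        ("econ.cost_cvd_acute_year", c.cost_cvd_acute_year),
        ("econ.cost_cvd_stable_year", c.cost_cvd_stable_year),
    ):
        specs[name] = DistributionSpec("gamma", mean, rel_se * mean)
    for name, mean in (
        ("econ.utility_healthy", c.utility_healthy),
        (f"econ.utility_htn.{MALE}", c.utility_htn[MALE]),
        (f"econ.utility_htn.{FEMALE}", c.utility_htn[FEMALE]),
        ("econ.utility_acute", c.utility_acute),
        (f"econ.utility_stable.{MALE}", c.utility_stable[MALE]),
        (f"econ.utility_stable.{FEMALE}", c.utility_stable[FEMALE]),
    ):
        specs[name] = DistributionSpec("beta", mean, rel_se * mean)
    specs["epi.rr_acute"] = DistributionSpec("lognormal", e.rr_acute, rel_se)
    specs["epi.rr_death"] = DistributionSpec("lognormal", e.rr_death, rel_se)
    specs[RISK_BLOCK] = DistributionSpec("cholesky")
    return specs


def draw_parameters(params: ParameterSet,
                    rng: np.random.Generator | int) -> ParameterSet:
    """One joint PSA draw of the parameter set (deterministic in the seed).

    Every entry of ``params.psa`` must name a distribution family; ``fixed``
    parameters pass through unchanged.  The risk coefficients are drawn
    jointly as mean + L z with L the Cholesky factor of their covariance.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    overrides: dict[str, float] = {}
    draw_risk = False
    for name in sorted(params.psa):
        spec = params.psa[name]
        if spec.family == "fixed":
            continue
        if spec.family == "cholesky":
            draw_risk = True
            continue
        if spec.family not in DistributionSpec.FAMILIES:
            raise ValueError(f"psa[{name}]: unknown family {spec.family!r}")
        if spec.mean is None or spec.se is None:
            raise ValueError(f"psa[{name}]: family {spec.family!r} needs mean and se")
        if spec.family == "gamma":
            shape, scale = gamma_from_moments(spec.mean, spec.se)
            overrides[name] = float(rng.gamma(shape) * scale)
        elif spec.family == "beta":
            a, b = beta_from_moments(spec.mean, spec.se)
            overrides[name] = float(rng.beta(a, b))
        elif spec.family == "lognormal":
            mu, sigma = lognormal_from_rr(spec.mean, spec.se)
            overrides[name] = float(rng.lognormal(mu, sigma))
    out = apply_overrides(params, overrides)
    if draw_risk:
        L = cholesky_factor(np.asarray(params.risk.covariance))
        z = rng.standard_normal(4)
        vec = params.risk.mean_vector() + L @ z
        r = out.risk
        r.intercept_nonfatal, r.intercept_fatal = float(vec[0]), float(vec[1])
        r.beta_age, r.beta_sex = float(vec[2]), float(vec[3])
        # printed values keep the fatal intercept below the non-fatal one;
        # degenerate draws violating it are reordered rather than rejected
        if r.intercept_fatal > r.intercept_nonfatal:
            r.intercept_nonfatal, r.intercept_fatal = (
                r.intercept_fatal, r.intercept_nonfatal)
    return out


# ---------------------------------------------------------------------------
# PSA runner

@dataclass
class PSASample:
    """Per-draw discounted (cost, QALY) pairs for each strategy.

    ``costs``/``qalys`` have shape (n_draws, n_strategies), per 1,000
    entrants; ``param_draws`` retains the sampled scalar parameters for
    diagnostics; ``n_truncated`` counts renormalized source states across
    all draws.
    """

    scenarios: list[Scenario]
    costs: np.ndarray
    qalys: np.ndarray
    seed: int
    specs: dict[str, DistributionSpec]
    param_draws: dict[str, np.ndarray] = field(default_factory=dict)
    n_truncated: int = 0

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def labels(self) -> list[str]:
        return [s.label() for s in self.scenarios]

    def index_of(self, strategy: str) -> int:
        for i, s in enumerate(self.scenarios):
            if s.strategy == strategy or s.label() == strategy:
                return i
        raise KeyError(f"no scenario with strategy/label {strategy!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, lab in enumerate(self.labels()):
            for i in range(self.n_draws):
                rows.append({"draw": i, "strategy": lab,
                             "cost": self.costs[i, j], "qaly": self.qalys[i, j]})
        return pd.DataFrame(rows)


_TRACKED = ("epi.rr_acute", "epi.rr_death", "econ.cost_screen_round",
            "econ.cost_htn_treat_year", "econ.cost_cvd_acute_year",
            "econ.utility_healthy", "econ.utility_acute")


def run_psa(scenarios: list[Scenario], params: ParameterSet, n: int,
            seed: int) -> PSASample:
    """Monte Carlo PSA: ``n`` joint parameter draws, each run through every
    scenario (common random parameters across strategies)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    S = len(scenarios)
    costs = np.zeros((n, S))
    qalys = np.zeros((n, S))
    tracked = {k: np.zeros(n) for k in _TRACKED if k in params.psa}
    n_trunc = 0
    for i in range(n):
        dp = draw_parameters(params, rng)
        for key, arr in tracked.items():
            parts = key.split(".")
            obj = dp
            for p in parts:
                obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
            arr[i] = obj
        for j, scen in enumerate(scenarios):
            trace = run_cohort(scen, dp, renormalize=True)
            n_trunc += trace.n_truncated
            res = accrue(trace, dp.econ)
            costs[i, j] = res.total_cost
            qalys[i, j] = res.total_qaly
    return PSASample(
        scenarios=list(scenarios), costs=costs, qalys=qalys, seed=seed,
        specs=dict(params.psa), param_draws=tracked, n_truncated=n_trunc,
    )


# ---------------------------------------------------------------------------
# CEAC

@dataclass(frozen=True)
class CEACurve:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray
    strategy: str
    comparator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability,
                             "strategy": self.strategy, "comparator": self.comparator})


def default_wtp_grid(params: ParameterSet, n_points: int = 101) -> np.ndarray:
    """0 to 4x GDP per capita; with 101 points the 3x GDP threshold is a
    grid point exactly.  Any explicit threshold override is inserted."""
    g = params.econ.gdp_per_capita
    grid = np.linspace(0.0, 4.0 * g, n_points)
    thr = wtp_threshold(g, params.econ.wtp_multiplier, params.econ.wtp_override)
    return np.unique(np.append(grid, thr))


def ceac(sample: PSASample, strategy: str, comparator: str,
         wtp_grid: np.ndarray) -> CEACurve:
    """CEAC by the net-monetary-benefit rule: at each threshold, the
    fraction of draws with lambda * dQALY - dCost >= 0."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0 or np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("wtp_grid must be nonempty and strictly increasing")
    i = sample.index_of(strategy)
    j = sample.index_of(comparator)
    de = sample.qalys[:, i] - sample.qalys[:, j]
    dc = sample.costs[:, i] - sample.costs[:, j]
    prob = np.array([(lam * de - dc >= 0.0).mean() for lam in wtp_grid])
    return CEACurve(wtp=wtp_grid, probability=prob,
                    strategy=sample.scenarios[i].label(),
                    comparator=sample.scenarios[j].label())


# ---------------------------------------------------------------------------
# Univariate (tornado) sensitivity analysis

GBD_PLAN_KEY = "gbd_utilities"
AGE_RR_PLAN_KEY = "age_dependent_rr"

#: default age-dependence of the treatment RR in the scenario analysis:
#: anchored at 55 so the composite RR there equals the base case, with log-RR
#: rising mildly in age (treatment relatively less protective when older)
DEFAULT_AGE_RR = {"anchor_age": 55.0, "log_slope": 0.005}


def default_sa_plan() -> dict[str, dict | str]:
    """The univariate perturbation plan: +/-25% on the CVD transition
    probability and unit costs, 10%/20% CVD utility decrements, 1%/3% QALY
    discounting, the GBD utility set, national-survey prevalence and the
    age-dependent treatment-RR mapping."""
    plan: dict[str, dict | str] = {"base_case": {}}
    for name, target in (
        ("cvd_transition_prob", "epi.cvd_prob_multiplier"),
        ("cost_screen", "econ.cost_screen_round"),
        ("cost_htn_treat", "econ.cost_htn_treat_year"),
        ("cost_cvd_acute", "econ.cost_cvd_acute_year"),
        ("cost_cvd_stable", "econ.cost_cvd_stable_year"),
    ):
        plan[f"{name}_-25pct"] = {target: {"mul": 0.75}}
        plan[f"{name}_+25pct"] = {target: {"mul": 1.25}}
    for pct, f in (("10", 0.9), ("20", 0.8)):
        plan[f"utility_cvd_-{pct}pct"] = {
            "econ.utility_acute": {"mul": f},
            f"econ.utility_stable.{MALE}": {"mul": f},
            f"econ.utility_stable.{FEMALE}": {"mul": f},
        }
    plan["discount_qaly_1pct"] = {"econ.discount_qaly": 0.01}
    plan["discount_qaly_3pct"] = {"econ.discount_qaly": 0.03}
    plan[GBD_PLAN_KEY] = GBD_PLAN_KEY
    plan["national_survey_prevalence"] = {"epi.prev_scale": {"mul": 1.25}}
    plan[AGE_RR_PLAN_KEY] = AGE_RR_PLAN_KEY
    return plan


def _comparator_for(scenario: Scenario) -> Scenario:
    return Scenario(sex=scenario.sex, start_age=scenario.start_age,
                    horizon=scenario.horizon, strategy="none")


def _run_icer(scenario: Scenario, params: ParameterSet,
              utility_set: dict[str, float] | None = None):
    res_i = accrue(run_cohort(scenario, params), params.econ, utility_set)
    res_0 = accrue(run_cohort(_comparator_for(scenario), params), params.econ,
                   utility_set)
    return icer(res_i, res_0)


def univariate_sa(scenario: Scenario, params: ParameterSet,
                  plan: dict[str, dict | str] | None = None) -> pd.DataFrame:
    """Deterministic one-way sensitivity analysis for one screening scenario.

    One model run per perturbation; rows report the ICER (or dominance),
    the shift from the base case and the threshold flag, ordered tornado
    style by |ICER - base| descending with alphabetical tie-breaking.
    """
    if plan is None:
        plan = default_sa_plan()
    if "base_case" not in plan:
        plan = {"base_case": {}, **plan}
    thr = wtp_threshold(params.econ.gdp_per_capita, params.econ.wtp_multiplier,
                        params.econ.wtp_override)
    rows = []
    for name, spec in plan.items():
        if spec == GBD_PLAN_KEY:
            out = _run_icer(scenario, params, utility_set=params.alt_utilities_gbd)
        elif spec == AGE_RR_PLAN_KEY:
            p2 = copy.deepcopy(params)
            p2.rr_age_dependence = dict(DEFAULT_AGE_RR)
            out = _run_icer(scenario, p2)
        elif isinstance(spec, dict):
            out = _run_icer(scenario, apply_overrides(params, spec))
        else:
            raise ValueError(f"unknown perturbation spec for {name!r}: {spec!r}")
        rows.append({
            "perturbation": name,
            "icer_kind": out.kind,
            "icer": out.value if out.kind == "ratio" else np.nan,
            "incr_cost": out.delta_cost,
            "incr_qaly": out.delta_qaly,
            "cost_effective": is_cost_effective(out, thr),
        })
    df = pd.DataFrame(rows)
    base_icer = df.loc[df["perturbation"] == "base_case", "icer"].iloc[0]
    df["abs_shift"] = (df["icer"] - base_icer).abs()
    body = df[df["perturbation"] != "base_case"].sort_values(
        ["abs_shift", "perturbation"], ascending=[False, True],
        na_position="last")
    head = df[df["perturbation"] == "base_case"]
    return pd.concat([head, body], ignore_index=True)
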