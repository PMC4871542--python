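"""Model parameters: definition, loading, validation and overrides.

The parameter set is the single source of truth for a model run.  It bundles

* the CVD risk-equation coefficients (log-rate linear predictor in age and
  sex, separate intercepts for non-fatal and fatal events),
* epidemiological inputs (hypertension prevalence split into a
  screen-detectable and a symptom-aware pool, treatment uptake, incidence,
  the acute-to-fatal probability, treatment relative risks),
* economic inputs (unit costs in international dollars, health-state
  utilities, discount rates, the willingness-to-pay rule),
* an all-cause life table, and
* a probabilistic-sensitivity-analysis block mapping parameters to
  sampling distributions.

Configuration files are YAML; a life table may alternatively be given as a
CSV with columns ``age,sex,q_crude``.  Optional blocks (life table,
prevalence, PSA) that are absent from a config are filled with documented
defaults: synthetic tables for the tables, all-``fixed`` specs for PSA.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: Default relative standard error for stochastic PSA parameters whose
#: dispersion is not otherwise specified (conventional placeholder,
#: configurable per parameter in the ``psa`` block).
DEFAULT_RELATIVE_SE = 0.20


class ParameterError(ValueError):
    """Raised when a configuration violates the parameter schema."""


#: Default SEs for the risk-equation coefficients
#: (intercept_nonfatal, intercept_fatal, beta_age, beta_sex), expressed on
#: the log-rate scale on which the coefficients act — matching the SD used
#: for log relative risks.  A relative SE on an intercept's magnitude would
#: depend on the arbitrary covariate centring and makes most draws
#: degenerate, so dispersion is anchored to the linear predictor instead.
RISK_COEF_DEFAULT_SE = (0.20, 0.20, 0.004, 0.10)


def _as_cov(values: Any, means: np.ndarray) -> np.ndarray:
    """Coerce a covariance block to a 4x4 array, defaulting to a diagonal
    built from ``RISK_COEF_DEFAULT_SE``."""
    if values is None:
        se = np.asarray(RISK_COEF_DEFAULT_SE)
        return np.diag(se**2)
    cov = np.asarray(values, dtype=float)
    if cov.shape != (4, 4):
        raise ParameterError(f"risk covariance must be 4x4, got {cov.shape}")
    return cov


@dataclass(eq=False)
class RiskCoefficients:
    """Log-rate CVD risk equation: rate = exp(c + b_age*age + b_sex*male).

    Separate intercepts parameterise non-fatal and fatal events; the age and
    sex coefficients are shared.  ``covariance`` is a joint 4x4 matrix over
    (intercept_nonfatal, intercept_fatal, beta_age, beta_sex) used for
    correlated PSA draws.  ``functional_form`` selects ``log_rate``
    (default) or ``logistic`` for the linear predictor.
    """

    intercept_nonfatal: float = -9.54
    intercept_fatal: float = -10.67
    beta_age: float = 0.07
    beta_sex: float = 0.55
    covariance: np.ndarray | None = None
    functional_form: str = "log_rate"

    def __post_init__(self) -> None:
        self.covariance = _as_cov(self.covariance, self.mean_vector())

    def mean_vector(self) -> np.ndarray:
        return np.array(
            [self.intercept_nonfatal, self.intercept_fatal, self.beta_age, self.beta_sex]
        )


@dataclass(eq=False)
class PrevalenceTable:
    """Age/sex hypertension prevalence, split into the pool detectable only
    by screening (unaware) and the symptom-aware (diagnosed) pool.

    ``ages`` are band-start ages; lookups use the last band whose start age
    does not exceed the query, clamped at both ends.
    """

    ages: np.ndarray
    total: dict[str, np.ndarray]
    screen_detect: dict[str, np.ndarray]
    aware: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        for d in (self.total, self.screen_detect, self.aware):
            for s in list(d):
                d[s] = np.asarray(d[s], dtype=float)

    def _idx(self, age: float) -> int:
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        return min(max(i, 0), len(self.ages) - 1)

    def lookup(self, age: float, sex: str) -> tuple[float, float, float]:
        """Return (total, screen_detectable, aware) prevalence at ``age``."""
        i = self._idx(age)
        return (
            float(self.total[sex][i]),
            float(self.screen_detect[sex][i]),
            float(self.aware[sex][i]),
        )


@dataclass(eq=False)
class LifeTable:
    """Annual all-cause death probabilities q(age, sex)."""

    ages: np.ndarray
    q: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        for s in list(self.q):
            self.q[s] = np.asarray(self.q[s], dtype=float)

    def q_crude(self, age: float, sex: str) -> float:
        i = int(np.searchsorted(self.ages, age, side="right")) - 1
        i = min(max(i, 0), len(self.ages) - 1)
        return float(self.q[sex][i])

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "sex", "q_crude"} - set(df.columns)
        if missing:
            raise ParameterError(f"life table CSV missing columns: {sorted(missing)}")
        ages = np.sort(df["age"].unique()).astype(float)
        q = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if len(sub) != len(ages):
                raise ParameterError(f"life table: one row per (age, sex) required ({sex})")
            q[sex] = sub["q_crude"].to_numpy(dtype=float)
        return cls(ages=ages, q=q)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for a, qv in zip(self.ages, self.q[sex]):
                rows.append({"age": a, "sex": sex, "q_crude": qv})
        return pd.DataFrame(rows)


@dataclass(eq=False)
class EpiInputs:
    """Epidemiological inputs.

    ``prev_scale`` uniformly rescales all prevalence pools (used by the
    national-survey prevalence scenario); ``cvd_prob_multiplier`` rescales
    the annual probabilities of non-fatal and fatal CVD from the risk
    equation (used by the +/-25% univariate sensitivity analysis).
    """

    prevalence: PrevalenceTable
    uptake: dict[str, float] = field(default_factory=lambda: {FEMALE: 0.62, MALE: 0.48})
    incidence_prob: dict[str, float] = field(
        default_factory=lambda: {FEMALE: 0.0065, MALE: 0.0164}
    )
    p_acute_to_fatal: float = 0.008
    cvd_death_fraction: float = 0.25
    rr_acute: float = 0.72
    rr_death: float = 0.82
    composite_stroke_weight: float = 0.78
    symptomatic_diagnosis_prob: float = 0.0
    prev_scale: float = 1.0
    cvd_prob_multiplier: float = 1.0
    #: whether the CVD-death relative risk also applies to the acute->fatal
    #: transition under treatment (default yes)
    rr_death_on_acute: bool = True


@dataclass(eq=False)
class EconInputs:
    """Costs (Int$, PPP-converted, 2013), utilities and discounting."""

    cost_screen_round: float = 6.05
    cost_htn_treat_year: float = 70.82
    cost_cvd_acute_year: float = 3723.24
    cost_cvd_stable_year: float = 79.39
    utility_healthy: float = 0.93
    utility_htn: dict[str, float] = field(default_factory=lambda: {MALE: 0.74, FEMALE: 0.71})
    utility_acute: float = 0.67
    utility_stable: dict[str, float] = field(default_factory=lambda: {MALE: 0.72, FEMALE: 0.71})
    discount_cost: float = 0.03
    discount_qaly: float = 0.0
    ppp_rate: float = 7546.6
    gdp_per_capita: float = 5294.0
    wtp_multiplier: float = 3.0
    #: explicit threshold override (Int$/QALY); None -> multiplier x GDP
    wtp_override: float | None = None


@dataclass(eq=False)
class Scenario:
    """A single model run: who is screened, how often, for how long.

    ``strategy`` is one of ``none``, ``one_off``, ``annual``, ``biannual``,
    ``biannual_then_annual`` (requires ``switch_age``).
    ``coverage_multiplier`` scales treatment uptake among the diagnosed
    (1.2 for the "+20%" scenarios); ``coverage_mode`` selects the relative
    reading (``relative``, uptake x multiplier, default) or the absolute one
    (``absolute``, uptake + (multiplier - 1)).
    """

    sex: str
    start_age: int
    horizon: str = "ten_year"  # "ten_year" | "lifetime"
    strategy: str = "none"
    switch_age: int | None = None
    coverage_multiplier: float = 1.0
    coverage_mode: str = "relative"

    STRATEGIES = ("none", "one_off", "annual", "biannual", "biannual_then_annual")

    def n_cycles(self, max_age: float = 100.0) -> int:
        if self.horizon == "ten_year":
            return 10
        if self.horizon == "lifetime":
            return max(int(max_age) - int(self.start_age), 0)
        raise ParameterError(f"unknown horizon {self.horizon!r}")

    def effective_uptake(self, uptake: float) -> float:
        if self.coverage_mode == "relative":
            u = uptake * self.coverage_multiplier
        elif self.coverage_mode == "absolute":
            u = uptake + (self.coverage_multiplier - 1.0)
        else:
            raise ParameterError(f"unknown coverage_mode {self.coverage_mode!r}")
        if u > 1.0 + 1e-12:
            raise ParameterError(
                f"effective uptake {u:.3f} exceeds 1 (uptake {uptake}, "
                f"multiplier {self.coverage_multiplier})"
            )
        return min(u, 1.0)

    def label(self) -> str:
        base = self.strategy
        if self.strategy == "biannual_then_annual":
            base = f"biannual_until_{self.switch_age}_then_annual"
        if self.coverage_multiplier != 1.0:
            base += f"+T{self.coverage_multiplier:g}"
        return f"{self.sex}/{self.start_age}/{self.horizon}/{base}"


def standard_scenarios(sex: str, start_age: int,
                       horizon: str = "ten_year") -> list[Scenario]:
    """The published scenario grid for one (sex, start age, horizon) cell.

    Ten-year: no screening, one-off, annual, biannual, and annual/biannual
    combined with +20% treatment coverage.  Lifetime: no screening, annual,
    biannual, biannual-until-55/60-then-annual, and the two +20% coverage
    combinations.
    """

    def s(strategy: str, mult: float = 1.0, switch: int | None = None) -> Scenario:
        return Scenario(sex=sex, start_age=start_age, horizon=horizon,
                        strategy=strategy, switch_age=switch,
                        coverage_multiplier=mult)

    if horizon == "ten_year":
        return [s("none"), s("one_off"), s("annual"), s("biannual"),
                s("annual", 1.2), s("biannual", 1.2)]
    if horizon == "lifetime":
        out = [s("none"), s("annual"), s("biannual")]
        for switch in (55, 60):
            if switch > start_age:
                out.append(s("biannual_then_annual", switch=switch))
        out += [s("annual", 1.2), s("biannual", 1.2)]
        return out
    raise ParameterError(f"unknown horizon {horizon!r}")


@dataclass(eq=False)
class DistributionSpec:
    """Sampling distribution for one parameter in the PSA.

    ``family`` is one of ``gamma`` (costs), ``beta`` (utilities and
    probabilities), ``lognormal`` (relative risks), ``cholesky`` (the joint
    normal over the risk-equation coefficients) or ``fixed``.  ``se`` is the
    standard error on the natural scale, except for ``lognormal`` where it
    is the SD of log(RR).
    """

    family: str
    mean: float | None = None
    se: float | None = None

    FAMILIES = ("gamma", "beta", "lognormal", "cholesky", "fixed")


#: GBD-derived alternative utility set (healthy, hypertension, acute CVD,
#: stable CVD) used in the international-comparison sensitivity analysis.
GBD_UTILITIES = {"healthy": 0.957, "htn": 0.835, "acute": 0.685, "stable": 0.717}


@dataclass(eq=False)
class ParameterSet:
    """The full input set for a run; see module docstring."""

    risk: RiskCoefficients
    epi: EpiInputs
    econ: EconInputs
    life_table: LifeTable
    psa: dict[str, DistributionSpec] = field(default_factory=dict)
    alt_utilities_gbd: dict[str, float] = field(default_factory=lambda: dict(GBD_UTILITIES))
    #: optional age-dependent treatment-RR mapping for scenario analysis:
    #: rr(age) = rr_base * exp(log_slope * (age - anchor_age))
    rr_age_dependence: dict[str, float] | None = None
    provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Validation

def _check(violations: list[str], ok: bool, msg: str) -> None:
    if not ok:
        violations.append(msg)


def validate(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid).

    Each entry names the offending field, its value and the rule broken.
    """
    v: list[str] = []
    r = params.risk
    cov = np.asarray(r.covariance, dtype=float)
    _check(v, np.allclose(cov, cov.T, atol=1e-10),
           "risk.covariance: matrix not symmetric")
    if np.allclose(cov, cov.T, atol=1e-10):
        _check(v, float(np.linalg.eigvalsh((cov + cov.T) / 2).min()) >= -1e-10,
               "risk.covariance: matrix not positive semi-definite")
    _check(v, np.isfinite(r.beta_age), f"risk.beta_age: {r.beta_age} not finite")
    _check(v, r.intercept_fatal <= r.intercept_nonfatal,
           f"risk.intercept_fatal: {r.intercept_fatal} exceeds intercept_nonfatal "
           f"{r.intercept_nonfatal} (fatal risk must not exceed non-fatal)")
    _check(v, r.functional_form in ("log_rate", "logistic"),
           f"risk.functional_form: unknown form {r.functional_form!r}")

    e = params.epi
    for sex in SEXES:
        u = e.uptake[sex]
        _check(v, 0.0 <= u <= 1.0, f"epi.uptake[{sex}]: {u} outside [0, 1]")
        inc = e.incidence_prob[sex]
        _check(v, 0.0 <= inc <= 1.0, f"epi.incidence_prob[{sex}]: {inc} outside [0, 1]")
    _check(v, 0.0 <= e.p_acute_to_fatal <= 1.0,
           f"epi.p_acute_to_fatal: {e.p_acute_to_fatal} outside [0, 1]")
    _check(v, 0.0 <= e.cvd_death_fraction <= 1.0,
           f"epi.cvd_death_fraction: {e.cvd_death_fraction} outside [0, 1]")
    _check(v, e.rr_acute > 0, f"epi.rr_acute: {e.rr_acute} not positive")
    _check(v, e.rr_death > 0, f"epi.rr_death: {e.rr_death} not positive")
    _check(v, 0.0 <= e.composite_stroke_weight <= 1.0,
           f"epi.composite_stroke_weight: {e.composite_stroke_weight} outside [0, 1]")
    prev = e.prevalence
    for sex in SEXES:
        for arr, name in ((prev.total[sex], "total"),
                          (prev.screen_detect[sex], "screen_detect"),
                          (prev.aware[sex], "aware")):
            _check(v, bool(np.all((arr >= 0) & (arr <= 1))),
                   f"epi.prevalence.{name}[{sex}]: values outside [0, 1]")
        s = prev.screen_detect[sex] + prev.aware[sex]
        _check(v, bool(np.all(s <= prev.total[sex] + 1e-9)),
               f"epi.prevalence[{sex}]: screen_detect + aware exceeds total "
               f"(max excess {float((s - prev.total[sex]).max()):.4g})")

    c = params.econ
    for name in ("cost_screen_round", "cost_htn_treat_year",
                 "cost_cvd_acute_year", "cost_cvd_stable_year"):
        val = getattr(c, name)
        _check(v, val >= 0, f"econ.{name}: {val} negative")
    for sex in SEXES:
        us = c.utility_stable[sex]
        uh = c.utility_htn[sex]
        _check(v, 0.0 <= uh <= 1.0, f"econ.utility_htn[{sex}]: {uh} outside [0, 1]")
        _check(v, 0.0 <= us <= 1.0, f"econ.utility_stable[{sex}]: {us} outside [0, 1]")
        _check(v, c.utility_acute <= us + 1e-12,
               f"econ.utility_acute: {c.utility_acute} exceeds utility_stable[{sex}] {us}")
        _check(v, us <= uh + 1e-12,
               f"econ.utility_stable[{sex}]: {us} exceeds utility_htn[{sex}] {uh}")
        _check(v, uh <= c.utility_healthy + 1e-12,
               f"econ.utility_htn[{sex}]: {uh} exceeds utility_healthy {c.utility_healthy}")
    _check(v, 0.0 <= c.utility_acute <= 1.0,
           f"econ.utility_acute: {c.utility_acute} outside [0, 1]")
    _check(v, 0.0 <= c.utility_healthy <= 1.0,
           f"econ.utility_healthy: {c.utility_healthy} outside [0, 1]")
    for name in ("discount_cost", "discount_qaly"):
        val = getattr(c, name)
        _check(v, 0.0 <= val <= 0.2, f"econ.{name}: {val} outside [0, 0.2]")

    lt = params.life_table
    for sex in SEXES:
        _check(v, bool(np.all((lt.q[sex] >= 0) & (lt.q[sex] <= 1))),
               f"life_table.q[{sex}]: values outside [0, 1]")
    _check(v, bool(np.all(np.diff(lt.ages) == 1)),
           "life_table.ages: ages not contiguous")

    for name, spec in params.psa.items():
        _check(v, spec.family in DistributionSpec.FAMILIES,
               f"psa[{name}].family: unknown family {spec.family!r}")
    return v


# ---------------------------------------------------------------------------
# Overrides

def _resolve(obj: Any, parts: list[str]) -> tuple[Any, str]:
    """Walk dotted-path ``parts`` to the parent container and final key."""
    for p in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[p]
        else:
            obj = getattr(obj, p)
    return obj, parts[-1]


def _get(obj: Any, key: str) -> Any:
    return obj[key] if isinstance(obj, dict) else getattr(obj, key)


def _set(obj: Any, key: str, value: Any) -> None:
    if isinstance(obj, dict):
        obj[key] = value
    else:
        setattr(obj, key, value)


def list_override_names(params: ParameterSet) -> list[str]:
    """Dotted paths of the scalar parameters that overrides may target."""
    names: list[str] = []
    for block in ("risk", "epi", "econ"):
        sub = getattr(params, block)
        for f in dataclasses.fields(sub):
            val = getattr(sub, f.name)
            if isinstance(val, (int, float)) and not isinstance(val, bool):
                names.append(f"{block}.{f.name}")
            elif isinstance(val, dict) and all(
                isinstance(x, (int, float)) for x in val.values()
            ):
                names.extend(f"{block}.{f.name}.{k}" for k in val)
    return names


def apply_overrides(params: ParameterSet, overrides: dict[str, Any]) -> ParameterSet:
    """Return a copy of ``params`` with the named overrides applied.

    An override value that is a plain number replaces the parameter; a
    mapping ``{"mul": f}`` multiplies it.  Unknown names raise a
    ``ParameterError`` listing valid targets.  The input set is untouched.
    """
    out = copy.deepcopy(params)
    valid = set(list_override_names(params))
    for name, spec in overrides.items():
        if name not in valid:
            raise ParameterError(
                f"unknown override target {name!r}; valid names: {sorted(valid)}"
            )
        parent, key = _resolve(out, name.split("."))
        if isinstance(spec, dict):
            if set(spec) != {"mul"}:
                raise ParameterError(f"override {name!r}: expected number or {{'mul': f}}")
            _set(parent, key, _get(parent, key) * float(spec["mul"]))
        else:
            _set(parent, key, float(spec))
    return out


# ---------------------------------------------------------------------------
# Serialization

def _table_to_dict(prev: PrevalenceTable) -> dict:
    return {
        "ages": prev.ages.tolist(),
        "total": {s: prev.total[s].tolist() for s in SEXES},
        "screen_detect": {s: prev.screen_detect[s].tolist() for s in SEXES},
        "aware": {s: prev.aware[s].tolist() for s in SEXES},
    }


def to_dict(params: ParameterSet) -> dict:
    """Plain-dict (YAML-safe) representation of a ParameterSet."""
    r = params.risk
    e = params.epi
    c = params.econ
    d: dict[str, Any] = {
        "risk": {
            "intercept_nonfatal": r.intercept_nonfatal,
            "intercept_fatal": r.intercept_fatal,
            "beta_age": r.beta_age,
            "beta_sex": r.beta_sex,
            "covariance": np.asarray(r.covariance).tolist(),
            "functional_form": r.functional_form,
        },
        "epi": {
            "prevalence": _table_to_dict(e.prevalence),
            "uptake": dict(e.uptake),
            "incidence_prob": dict(e.incidence_prob),
            "p_acute_to_fatal": e.p_acute_to_fatal,
            "cvd_death_fraction": e.cvd_death_fraction,
            "rr_acute": e.rr_acute,
            "rr_death": e.rr_death,
            "composite_stroke_weight": e.composite_stroke_weight,
            "symptomatic_diagnosis_prob": e.symptomatic_diagnosis_prob,
            "prev_scale": e.prev_scale,
            "cvd_prob_multiplier": e.cvd_prob_multiplier,
            "rr_death_on_acute": e.rr_death_on_acute,
        },
        "econ": {f.name: getattr(c, f.name) for f in dataclasses.fields(c)},
        "life_table": {
            "ages": params.life_table.ages.tolist(),
            "q": {s: params.life_table.q[s].tolist() for s in SEXES},
        },
        "psa": {
            name: {"family": s.family, "mean": s.mean, "se": s.se}
            for name, s in params.psa.items()
        },
        "alt_utilities_gbd": dict(params.alt_utilities_gbd),
        "rr_age_dependence": (
            dict(params.rr_age_dependence) if params.rr_age_dependence else None
        ),
        "provenance": dict(params.provenance),
    }
    d["econ"]["utility_htn"] = dict(c.utility_htn)
    d["econ"]["utility_stable"] = dict(c.utility_stable)
    return d


def from_dict(d: dict) -> ParameterSet:
    """Build a ParameterSet from a plain dict, filling documented defaults.

    Missing ``life_table``/``epi.prevalence`` blocks fall back to the
    synthetic defaults; a missing ``psa`` block yields all-``fixed`` specs.
    Raises ``ParameterError`` naming the field on schema violations.
    """
    from . import synthetic  # deferred: synthetic builds on these types

    try:
        risk = RiskCoefficients(**d.get("risk", {}))
    except TypeError as err:
        raise ParameterError(f"risk block: {err}") from None

    epi_d = dict(d.get("epi", {}))
    prev_d = epi_d.pop("prevalence", None)
    if prev_d is None:
        prevalence = synthetic.synth_prevalence(synthetic.SyntheticSpec())
    else:
        prevalence = PrevalenceTable(
            ages=prev_d["ages"],
            total={s: prev_d["total"][s] for s in SEXES},
            screen_detect={s: prev_d["screen_detect"][s] for s in SEXES},
            aware={s: prev_d["aware"][s] for s in SEXES},
        )
    try:
        epi = EpiInputs(prevalence=prevalence, **epi_d)
    except TypeError as err:
        raise ParameterError(f"epi block: {err}") from None

    try:
        econ = EconInputs(**d.get("econ", {}))
    except TypeError as err:
        raise ParameterError(f"econ block: {err}") from None

    lt_d = d.get("life_table")
    if lt_d is None:
        life_table = synthetic.synth_life_table(synthetic.SyntheticSpec())
    elif isinstance(lt_d, dict) and "csv" in lt_d:
        life_table = LifeTable.from_csv(lt_d["csv"])
    else:
        life_table = LifeTable(ages=lt_d["ages"], q={s: lt_d["q"][s] for s in SEXES})

    psa = {
        name: DistributionSpec(**spec) for name, spec in (d.get("psa") or {}).items()
    }
    ps = ParameterSet(
        risk=risk,
        epi=epi,
        econ=econ,
        life_table=life_table,
        psa=psa,
        alt_utilities_gbd=d.get("alt_utilities_gbd") or dict(GBD_UTILITIES),
        rr_age_dependence=d.get("rr_age_dependence"),
        provenance=d.get("provenance") or {},
    )
    if "psa" not in d:
        # documented default: every stochastic parameter present, all fixed
        from .uncertainty import default_psa_specs

        ps.psa = {
            name: DistributionSpec("fixed", spec.mean, spec.se)
            for name, spec in default_psa_specs(ps).items()
        }
    problems = validate(ps)
    if problems:
        raise ParameterError("invalid parameter set:\n  " + "\n  ".join(problems))
    return ps


def basecase_config_path() -> Path:
    """Path of the packaged base-case YAML config."""
    return Path(__file__).parent / "data" / "basecase.yaml"


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a fully populated ParameterSet from a YAML config file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return from_dict(d)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write ``params`` to YAML such that ``load_parameters`` round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False)


def params_equal(a: ParameterSet, b: ParameterSet, rtol: float = 0.0,
                 atol: float = 1e-12) -> bool:
    """Structural equality of two parameter sets (arrays compared elementwise)."""

    def eq(x: Any, y: Any) -> bool:
        if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
            return np.allclose(np.asarray(x, float), np.asarray(y, float),
                               rtol=rtol, atol=atol)
        if isinstance(x, dict):
            return set(x) == set(y) and all(eq(x[k], y[k]) for k in x)
        if isinstance(x, float) and isinstance(y, float):
            return abs(x - y) <= atol + rtol * abs(y)
        return x == y

    da, db = to_dict(a), to_dict(b)
    return eq(da, db)
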