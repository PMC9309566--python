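"""Typed model inputs for the BRCA1/2 testing cost-effectiveness model.

Everything the model consumes lives in one :class:`ParameterSet`: annual
transition probabilities (some age-banded, some tunnel-year schedules),
health-state utility multipliers, and annual costs in 2021 Brazilian reais
(R$), together with the economic settings (5% discount rate, 70 one-year
cycles starting at age 30).  The shipped ``data/basecase.yaml`` is the single
source of truth for the base case; sensitivity analyses always work on deep
copies obtained through :func:`set_path` overrides.

Three derived transformations are provided here because they belong to the
inputs rather than the engine:

* :func:`cumulative_to_conditional` — the printed five-year mortality
  schedules for metastatic breast cancer and ovarian cancer are cumulative
  (Kaplan–Meier output); the Markov engine needs per-cycle conditional
  probabilities ``cond[t] = (cum[t] - cum[t-1]) / (1 - cum[t-1])``.
* :func:`test_cost_per_woman` — the genetic test is priced per family
  (one index case plus ``n`` relatives) and averaged to a per-woman cost.
* :func:`fit_distribution` — method-of-moments beta/gamma fits used by the
  probabilistic sensitivity analysis.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, fields, is_dataclass
from importlib import resources
from typing import Any, Optional, Sequence

import numpy as np
import yaml


# ---------------------------------------------------------------------------
# age-banded rates and tunnel schedules
# ---------------------------------------------------------------------------

@dataclass
class Band:
    lo: int
    hi: Optional[int]  # inclusive upper age; None = open-ended
    p: float

    def contains(self, age: float) -> bool:
        return age >= self.lo and (self.hi is None or age <= self.hi)


@dataclass
class AgeBandedRate:
    """Annual probability defined on contiguous age bands from age 30 up."""

    bands: list[Band]

    def lookup(self, age: float) -> float:
        for b in self.bands:
            if b.contains(age):
                return b.p
        raise KeyError(f"age {age} not covered by any band")

    def as_array(self, start_age: int, horizon: int) -> np.ndarray:
        """Per-cycle probability vector for ages start_age .. start_age+horizon-1."""
        return np.array([self.lookup(start_age + t) for t in range(horizon)])

    def validate(self, path: str, findings: list["Finding"],
                 start_age: int = 30, max_age: int = 100) -> None:
        prev_hi = start_age - 1
        for i, b in enumerate(self.bands):
            if not 0.0 <= b.p <= 1.0:
                findings.append(Finding(f"{path}.bands.{i}.p",
                                        f"probability {b.p} outside [0,1]"))
            if b.lo != prev_hi + 1:
                findings.append(Finding(f"{path}.bands.{i}",
                                        f"band starts at {b.lo}, expected {prev_hi + 1}"))
            prev_hi = b.hi if b.hi is not None else max_age
        if prev_hi < max_age - 1:
            findings.append(Finding(path, f"bands end at {prev_hi}, do not cover age {max_age - 1}"))


@dataclass
class CumulativeSchedule:
    """Cumulative event probability at the end of tunnel years 1..5.

    ``tail`` is the policy for years beyond the fifth tunnel year:
    ``"hold"`` keeps the year-5 conditional probability constant (metastatic
    breast cancer stays a terminal chain), ``"none"`` drops the excess hazard
    (ovarian-cancer survivors move to the post-cancer state where only
    background mortality applies).
    """

    cum: list[float]
    tail: str = "hold"  # "hold" | "none"

    def validate(self, path: str, findings: list["Finding"]) -> None:
        if len(self.cum) != 5:
            findings.append(Finding(path, f"schedule has {len(self.cum)} entries, expected 5"))
        prev = 0.0
        for i, c in enumerate(self.cum):
            if not 0.0 <= c <= 1.0:
                findings.append(Finding(f"{path}.cum.{i}", f"value {c} outside [0,1]"))
            if c < prev - 1e-12:
                findings.append(Finding(f"{path}.cum.{i}",
                                        f"cumulative schedule decreases at year {i + 1}"))
            prev = c
        if self.tail not in ("hold", "none"):
            findings.append(Finding(f"{path}.tail", f"unknown tail policy {self.tail!r}"))


@dataclass
class ConditionalSchedule:
    """Per-cycle conditional probabilities for tunnel years 1..5 plus a tail."""

    cond: list[float]
    tail: float

    def at_year(self, year: int) -> float:
        """Conditional probability for tunnel year ``year`` (1-based)."""
        if year < 1:
            raise ValueError("tunnel years are 1-based")
        return self.cond[year - 1] if year <= len(self.cond) else self.tail


def cumulative_to_conditional(sched: CumulativeSchedule) -> ConditionalSchedule:
    """Convert a cumulative KM-style schedule into per-cycle conditional probabilities.

    ``cond[t] = (cum[t] - cum[t-1]) / (1 - cum[t-1])``; applying the result
    sequentially to a unit cohort reproduces the cumulative schedule exactly.
    """
    cond: list[float] = []
    prev = 0.0
    for i, c in enumerate(sched.cum):
        if c < prev - 1e-12:
            raise ValueError(f"cumulative schedule not monotone at year {i + 1}: "
                             f"{c} < {prev}")
        if prev >= 1.0:
            warnings.warn(f"cumulative schedule reaches 1.0 before year {i + 1}; "
                          "remaining conditional probabilities set to 1")
            cond.append(1.0)
            continue
        cond.append((c - prev) / (1.0 - prev))
        prev = c
    tail = cond[-1] if sched.tail == "hold" else 0.0
    return ConditionalSchedule(cond=cond, tail=tail)


def conditional_schedule(sched: CumulativeSchedule, form: str) -> ConditionalSchedule:
    """Per-cycle schedule under either reading of the printed five-year table.

    ``form="conditional"`` uses the printed values directly as per-cycle
    tunnel probabilities; ``form="cumulative"`` converts cumulative KM
    incidence with :func:`cumulative_to_conditional`.
    """
    if form == "cumulative":
        return cumulative_to_conditional(sched)
    if form == "conditional":
        cond = list(sched.cum)
        tail = cond[-1] if sched.tail == "hold" else 0.0
        return ConditionalSchedule(cond=cond, tail=tail)
    raise ValueError(f"unknown schedule form {form!r}")


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class UptakeBlock:
    """Choice of risk-reducing option among women who test positive."""
    mastectomy: float = 0.03
    oophorectomy: float = 0.12
    both: float = 0.12

    @property
    def surveillance(self) -> float:
        return 1.0 - self.mastectomy - self.oophorectomy - self.both


@dataclass
class PostSurgeryRisks:
    """Residual cancer incidence after each risk-reducing surgery.

    Scalars are constant annual probabilities; the breast-cancer risk after
    oophorectomy alone stays age-banded (oophorectomy does not remove the
    breasts — the registry shows carrier-level risk, first band 0.014).
    """
    bc_after_mastectomy: float = 0.0
    bc_after_oophorectomy: AgeBandedRate | float = 0.0
    bc_after_both: float = 0.0
    oc_after_mastectomy: float = 0.0
    oc_after_oophorectomy: float = 0.01
    oc_after_both: float = 0.0


@dataclass
class ProbabilityBlock:
    #: how the printed five-year mortality schedules are read: "conditional"
    #: (per-cycle tunnel probabilities, the default) or "cumulative"
    #: (KM cumulative incidence, converted via cumulative_to_conditional)
    schedule_form: str
    p_positive_test: float
    uptake: UptakeBlock
    well_to_bc_carrier: AgeBandedRate
    well_to_bc_noncarrier: AgeBandedRate
    well_to_oc_carrier: float
    well_to_oc_noncarrier: float
    all_cause_mortality: AgeBandedRate
    recurrence_bc_carrier: float
    recurrence_bc_noncarrier: float
    bc_mortality: float
    bc_to_metastatic: float
    bc_to_oc: float
    metastatic_death: CumulativeSchedule
    oc_death: CumulativeSchedule
    post_surgery: PostSurgeryRisks


@dataclass
class SurgeryUtility:
    multiplier: float
    recovery_increment: float  # absolute utility added per tunnel year, years 2-5


@dataclass
class CancerUtility:
    multiplier: float        # first year after diagnosis
    post_multiplier: float   # steady post-cancer state, year 6 on
    recovery_increment: float


@dataclass
class UtilityBlock:
    baseline_age30: float = 0.920
    annual_age_decrement: float = 0.00029
    multiplier_high_risk: float = 0.92
    multiplier_negative: float = 1.0
    multiplier_untested: float = 1.0
    mastectomy: SurgeryUtility = field(default_factory=lambda: SurgeryUtility(0.88, 0.008))
    oophorectomy: SurgeryUtility = field(default_factory=lambda: SurgeryUtility(0.95, -0.0069))
    both: SurgeryUtility = field(default_factory=lambda: SurgeryUtility(0.83, 0.02))
    bc: CancerUtility = field(default_factory=lambda: CancerUtility(0.77, 0.79, 0.0021))
    metastatic: float = 0.64
    oc: CancerUtility = field(default_factory=lambda: CancerUtility(0.34, 0.83, 0.111))

    def baseline(self, age: float) -> float:
        return self.baseline_age30 - self.annual_age_decrement * (age - 30.0)


@dataclass
class SurgeryCosts:
    mastectomy: float = 3484.26
    oophorectomy: float = 621.00
    both: float = 4105.26


@dataclass
class CostBlock:
    index_test: float = 1800.0
    relative_test: float = 235.0
    n_relatives_per_index: int = 2
    intensive_screening_annual: float = 428.85
    standard_care_annual: float = 55.00
    surgery: SurgeryCosts = field(default_factory=SurgeryCosts)
    bc_index_yearly: list[float] = field(default_factory=list)
    bc_relative_yearly: list[float] = field(default_factory=list)
    metastatic_yearly: list[float] = field(default_factory=list)
    oc_yearly: list[float] = field(default_factory=list)

    @property
    def test_cost(self) -> float:
        return test_cost_per_woman(self.index_test, self.relative_test,
                                   self.n_relatives_per_index)


@dataclass
class ModelSettings:
    start_age: int = 30
    horizon_years: int = 70
    cycle_length: float = 1.0
    discount_rate: float = 0.05


@dataclass
class UncertaintySpec:
    """Uncertainty attached to one scalar parameter, addressed by dotted path."""
    path: str
    family: str                     # "beta" | "gamma" | "fixed"
    sd: Optional[float] = None
    lo: Optional[float] = None      # 95% CI bounds; sd = (hi - lo) / 3.92
    hi: Optional[float] = None
    cv: Optional[float] = None      # coefficient of variation (costs: 0.4)

    def resolved_sd(self, mean: float) -> float:
        if self.sd is not None:
            return self.sd
        if self.lo is not None and self.hi is not None:
            return (self.hi - self.lo) / 3.92
        if self.cv is not None:
            return self.cv * mean
        raise ValueError(f"uncertainty for {self.path} has no sd, range, or cv")


@dataclass
class ParameterSet:
    model: ModelSettings
    probabilities: ProbabilityBlock
    utilities: UtilityBlock
    costs: CostBlock
    uncertainty: list[UncertaintySpec] = field(default_factory=list)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def test_cost_per_woman(cost_index: float, cost_relative: float,
                        n_relatives: int) -> float:
    """Average per-woman cost of testing one family: one index plus n relatives.

    The index test (NGS + MLPA, R$ 1,800) establishes the family variant;
    relatives are tested for the known variant at R$ 235.  The per-woman unit
    cost is the family total divided by the number of relatives who can be
    offered the predictive test.
    """
    if n_relatives < 1:
        raise ValueError("n_relatives must be >= 1; index-only testing is not modelled")
    if cost_index < 0 or cost_relative < 0:
        raise ValueError("costs must be non-negative")
    return (cost_index + n_relatives * cost_relative) / n_relatives


@dataclass
class DistributionSpec:
    family: str               # "beta" | "gamma" | "fixed"
    params: dict[str, float]
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        if self.family == "fixed":
            return np.full(size, self.mean) if size is not None else self.mean
        raise ValueError(f"unknown family {self.family!r}")

    def analytic_mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        return self.mean


def fit_distribution(mean: float, sd: Optional[float] = None,
                     lo: Optional[float] = None, hi: Optional[float] = None,
                     family: str = "beta") -> DistributionSpec:
    """Method-of-moments beta/gamma fit for PSA sampling.

    Printed (lo, hi) intervals are read as 95% CIs, so sd = (hi - lo)/3.92.
    An infeasible beta sd (sd^2 >= mean(1-mean)) is shrunk to 0.999 of the
    feasible bound with a warning.
    """
    if sd is None:
        if lo is None or hi is None:
            raise ValueError("provide sd or a (lo, hi) range")
        sd = (hi - lo) / 3.92
    if family == "fixed" or sd == 0:
        return DistributionSpec("fixed", {}, mean, 0.0)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta requires mean in (0,1), got {mean}")
        bound = math.sqrt(mean * (1.0 - mean))
        if sd >= bound:
            warnings.warn(f"beta sd {sd} infeasible for mean {mean}; "
                          f"shrunk to 0.999 * {bound:.6g}")
            sd = 0.999 * bound
        a = mean * (mean * (1.0 - mean) / sd**2 - 1.0)
        b = a * (1.0 - mean) / mean
        return DistributionSpec("beta", {"a": a, "b": b}, mean, sd)
    if family == "gamma":
        if mean <= 0:
            raise ValueError(f"gamma requires mean > 0, got {mean}")
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return DistributionSpec("gamma", {"shape": shape, "scale": scale}, mean, sd)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# dotted-path access (DSA overrides, PSA sampling, CLI --set)
# ---------------------------------------------------------------------------

def _step(obj: Any, key: str) -> Any:
    if isinstance(obj, (list, tuple)):
        return obj[int(key)]
    if isinstance(obj, dict):
        return obj[key]
    return getattr(obj, key)


def get_path(obj: Any, path: str) -> Any:
    """Read a value addressed by a dotted path, e.g. ``costs.bc_index_yearly.0``."""
    for key in path.split("."):
        obj = _step(obj, key)
    return obj


def set_path(obj: Any, path: str, value: Any) -> None:
    """Assign through a dotted path, casting strings to the existing value's type."""
    keys = path.split(".")
    for key in keys[:-1]:
        obj = _step(obj, key)
    last = keys[-1]
    current = _step(obj, last)
    if isinstance(value, str) and not isinstance(current, str):
        if isinstance(current, bool):
            value = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int) and not isinstance(current, bool):
            value = int(value)
        elif isinstance(current, float):
            value = float(value)
    if isinstance(obj, (list,)):
        obj[int(last)] = value
    elif isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    path: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"


def _check_prob(value: float, path: str, findings: list[Finding]) -> None:
    if not 0.0 <= value <= 1.0:
        findings.append(Finding(path, f"probability {value} outside [0,1]"))


def validate(params: ParameterSet) -> list[Finding]:
    """Validate every invariant of a ParameterSet; returns findings, never raises."""
    f: list[Finding] = []
    m = params.model
    if m.discount_rate < 0:
        f.append(Finding("model.discount_rate", "discount_rate < 0"))
    if m.horizon_years < 1:
        f.append(Finding("model.horizon_years", "horizon must be >= 1"))
    if m.cycle_length != 1.0:
        f.append(Finding("model.cycle_length", "only 1-year cycles are supported"))

    p = params.probabilities
    if p.schedule_form not in ("conditional", "cumulative"):
        f.append(Finding("probabilities.schedule_form",
                         f"unknown schedule form {p.schedule_form!r}"))
    _check_prob(p.p_positive_test, "probabilities.p_positive_test", f)
    u = p.uptake
    for name in ("mastectomy", "oophorectomy", "both"):
        _check_prob(getattr(u, name), f"probabilities.uptake.{name}", f)
    if u.mastectomy + u.oophorectomy + u.both > 1.0 + 1e-12:
        f.append(Finding("probabilities.uptake", "uptake sum > 1"))
    max_age = m.start_age + m.horizon_years
    p.well_to_bc_carrier.validate("probabilities.well_to_bc_carrier", f, max_age=max_age)
    p.well_to_bc_noncarrier.validate("probabilities.well_to_bc_noncarrier", f, max_age=max_age)
    p.all_cause_mortality.validate("probabilities.all_cause_mortality", f, max_age=max_age)
    for name in ("well_to_oc_carrier", "well_to_oc_noncarrier", "recurrence_bc_carrier",
                 "recurrence_bc_noncarrier", "bc_mortality", "bc_to_metastatic", "bc_to_oc"):
        _check_prob(getattr(p, name), f"probabilities.{name}", f)
    p.metastatic_death.validate("probabilities.metastatic_death", f)
    p.oc_death.validate("probabilities.oc_death", f)
    ps = p.post_surgery
    for name in ("bc_after_mastectomy", "bc_after_both", "oc_after_mastectomy",
                 "oc_after_oophorectomy", "oc_after_both"):
        _check_prob(getattr(ps, name), f"probabilities.post_surgery.{name}", f)
    if isinstance(ps.bc_after_oophorectomy, AgeBandedRate):
        ps.bc_after_oophorectomy.validate(
            "probabilities.post_surgery.bc_after_oophorectomy", f, max_age=max_age)
    else:
        _check_prob(ps.bc_after_oophorectomy,
                    "probabilities.post_surgery.bc_after_oophorectomy", f)

    ut = params.utilities
    if not 0.0 < ut.baseline_age30 <= 1.0:
        f.append(Finding("utilities.baseline_age30", "baseline must be in (0,1]"))
    for name in ("multiplier_high_risk", "multiplier_negative", "multiplier_untested",
                 "metastatic"):
        v = getattr(ut, name)
        if not 0.0 < v <= 1.0:
            f.append(Finding(f"utilities.{name}", f"multiplier {v} outside (0,1]"))
    for name in ("mastectomy", "oophorectomy", "both"):
        s = getattr(ut, name)
        if not 0.0 < s.multiplier <= 1.0:
            f.append(Finding(f"utilities.{name}.multiplier", "multiplier outside (0,1]"))
    for name in ("bc", "oc"):
        c = getattr(ut, name)
        for attr in ("multiplier", "post_multiplier"):
            if not 0.0 < getattr(c, attr) <= 1.0:
                f.append(Finding(f"utilities.{name}.{attr}", "multiplier outside (0,1]"))
        if c.recovery_increment < 0:
            f.append(Finding(f"utilities.{name}.recovery_increment",
                             "recovery increment < 0"))

    c = params.costs
    for name in ("index_test", "relative_test", "intensive_screening_annual",
                 "standard_care_annual"):
        if getattr(c, name) < 0:
            f.append(Finding(f"costs.{name}", "cost < 0"))
    if c.n_relatives_per_index < 1:
        f.append(Finding("costs.n_relatives_per_index", "must be >= 1"))
    for name in ("mastectomy", "oophorectomy", "both"):
        if getattr(c.surgery, name) < 0:
            f.append(Finding(f"costs.surgery.{name}", "cost < 0"))
    for name in ("bc_index_yearly", "bc_relative_yearly", "metastatic_yearly", "oc_yearly"):
        sched = getattr(c, name)
        if len(sched) != 5:
            f.append(Finding(f"costs.{name}", f"schedule has {len(sched)} entries, expected 5"))
        for i, v in enumerate(sched):
            if v < 0:
                f.append(Finding(f"costs.{name}.{i}", "cost < 0"))

    for spec in params.uncertainty:
        try:
            get_path(params, spec.path)
        except (AttributeError, KeyError, IndexError):
            f.append(Finding(f"uncertainty[{spec.path}]", "path does not resolve"))
        if spec.family not in ("beta", "gamma", "fixed"):
            f.append(Finding(f"uncertainty[{spec.path}]", f"unknown family {spec.family!r}"))
    return f


# ---------------------------------------------------------------------------
# YAML loading
# ---------------------------------------------------------------------------

def _banded(raw: Any) -> AgeBandedRate | float:
    if isinstance(raw, (int, float)):
        return float(raw)
    return AgeBandedRate(bands=[Band(lo=int(b[0]),
                                     hi=None if b[1] is None else int(b[1]),
                                     p=float(b[2])) for b in raw["bands"]])


def params_from_dict(d: dict) -> ParameterSet:
    mp = d.get("model", {})
    model = ModelSettings(start_age=int(mp.get("start_age", 30)),
                          horizon_years=int(mp.get("horizon_years", 70)),
                          cycle_length=float(mp.get("cycle_length", 1.0)),
                          discount_rate=float(mp.get("discount_rate", 0.05)))
    pp = d["probabilities"]
    probs = ProbabilityBlock(
        schedule_form=str(pp.get("schedule_form", "conditional")),
        p_positive_test=float(pp["p_positive_test"]),
        uptake=UptakeBlock(**{k: float(v) for k, v in pp["uptake"].items()}),
        well_to_bc_carrier=_banded(pp["well_to_bc_carrier"]),
        well_to_bc_noncarrier=_banded(pp["well_to_bc_noncarrier"]),
        well_to_oc_carrier=float(pp["well_to_oc_carrier"]),
        well_to_oc_noncarrier=float(pp["well_to_oc_noncarrier"]),
        all_cause_mortality=_banded(pp["all_cause_mortality"]),
        recurrence_bc_carrier=float(pp["recurrence_bc_carrier"]),
        recurrence_bc_noncarrier=float(pp["recurrence_bc_noncarrier"]),
        bc_mortality=float(pp["bc_mortality"]),
        bc_to_metastatic=float(pp["bc_to_metastatic"]),
        bc_to_oc=float(pp["bc_to_oc"]),
        metastatic_death=CumulativeSchedule(
            cum=[float(x) for x in pp["metastatic_death_cum"]], tail="hold"),
        oc_death=CumulativeSchedule(
            cum=[float(x) for x in pp["oc_death_cum"]], tail="none"),
        post_surgery=PostSurgeryRisks(
            bc_after_mastectomy=float(pp["post_surgery"]["bc_after_mastectomy"]),
            bc_after_oophorectomy=_banded(pp["post_surgery"]["bc_after_oophorectomy"]),
            bc_after_both=float(pp["post_surgery"]["bc_after_both"]),
            oc_after_mastectomy=float(pp["post_surgery"]["oc_after_mastectomy"]),
            oc_after_oophorectomy=float(pp["post_surgery"]["oc_after_oophorectomy"]),
            oc_after_both=float(pp["post_surgery"]["oc_after_both"]),
        ),
    )
    up = d["utilities"]
    utils = UtilityBlock(
        baseline_age30=float(up["baseline_age30"]),
        annual_age_decrement=float(up["annual_age_decrement"]),
        multiplier_high_risk=float(up["multiplier_high_risk"]),
        multiplier_negative=float(up.get("multiplier_negative", 1.0)),
        multiplier_untested=float(up.get("multiplier_untested", 1.0)),
        mastectomy=SurgeryUtility(**{k: float(v) for k, v in up["mastectomy"].items()}),
        oophorectomy=SurgeryUtility(**{k: float(v) for k, v in up["oophorectomy"].items()}),
        both=SurgeryUtility(**{k: float(v) for k, v in up["both"].items()}),
        bc=CancerUtility(**{k: float(v) for k, v in up["bc"].items()}),
        metastatic=float(up["metastatic"]),
        oc=CancerUtility(**{k: float(v) for k, v in up["oc"].items()}),
    )
    cp = d["costs"]
    costs = CostBlock(
        index_test=float(cp["index_test"]),
        relative_test=float(cp["relative_test"]),
        n_relatives_per_index=int(cp["n_relatives_per_index"]),
        intensive_screening_annual=float(cp["intensive_screening_annual"]),
        standard_care_annual=float(cp["standard_care_annual"]),
        surgery=SurgeryCosts(**{k: float(v) for k, v in cp["surgery"].items()}),
        bc_index_yearly=[float(x) for x in cp["bc_index_yearly"]],
        bc_relative_yearly=[float(x) for x in cp["bc_relative_yearly"]],
        metastatic_yearly=[float(x) for x in cp["metastatic_yearly"]],
        oc_yearly=[float(x) for x in cp["oc_yearly"]],
    )
    unc = [UncertaintySpec(path=e["path"], family=e["family"],
                           sd=e.get("sd"), lo=e.get("lo"), hi=e.get("hi"),
                           cv=e.get("cv"))
           for e in d.get("uncertainty", [])]
    return ParameterSet(model=model, probabilities=probs, utilities=utils,
                        costs=costs, uncertainty=unc)


def load_parameters(path: Optional[str] = None,
                    overrides: Sequence[str] = ()) -> ParameterSet:
    """Load a ParameterSet from YAML (the packaged base case when path is None).

    ``overrides`` are ``dotted.path=value`` strings applied after loading.
    """
    if path is None:
        text = resources.files("hboc_cea").joinpath("data/basecase.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params = params_from_dict(yaml.safe_load(text))
    for ov in overrides:
        key, _, value = ov.partition("=")
        if not _:
            raise ValueError(f"override {ov!r} is not of the form path=value")
        set_path(params, key.strip(), value.strip())
    return params
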