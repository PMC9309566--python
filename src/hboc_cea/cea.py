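"""Incremental cost-effectiveness analysis, deterministic and probabilistic.

* :func:`compute_icer` — incremental cost, QALYs and life years between the
  testing and no-testing strategies, with dominance classification; ICERs
  are always computed on unrounded totals.
* :func:`run_dsa` — one-way deterministic sensitivity analysis: each
  scenario sets (or scales) one parameter to its low and high bound, re-runs
  both arms, and records the ICER per QALY; output is tornado-ordered.
* :func:`run_psa` — probabilistic sensitivity analysis: every uncertain
  parameter is drawn independently from its fitted beta (probabilities,
  utilities) or gamma (costs, 40% CV) distribution, both arms are re-run per
  draw, and the (Δcost, ΔQALY) cloud yields the cost-effectiveness
  acceptability curve (CEAC) and incremental net monetary benefit
  INMB(λ) = λ·mean(ΔQALY) − mean(Δcost) over a willingness-to-pay grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .params import (ParameterSet, UncertaintySpec, fit_distribution,
                     get_path, set_path)
from .strategy import StrategyResult, evaluate_strategy

DEFAULT_WTP_GRID = np.arange(0.0, 150_500.0, 500.0)


@dataclass
class CEResult:
    reference: StrategyResult        # the testing strategy
    comparator: StrategyResult       # no testing
    d_cost: float
    d_qaly: float
    d_ly: float
    dominance: str                   # "tradeoff" | "dominant" | "dominated"
    icer_qaly: Optional[float]
    icer_ly: Optional[float]

    def to_dict(self) -> dict:
        return {
            "reference": self.reference.to_dict(),
            "comparator": self.comparator.to_dict(),
            "incremental": {"cost": self.d_cost, "qaly": self.d_qaly, "ly": self.d_ly},
            "dominance": self.dominance,
            "icer_per_qaly": self.icer_qaly,
            "icer_per_ly": self.icer_ly,
        }


def compute_icer(reference: StrategyResult, comparator: StrategyResult) -> CEResult:
    """Incremental analysis of reference vs comparator on unrounded totals."""
    d_cost = reference.cost - comparator.cost
    d_qaly = reference.qaly - comparator.qaly
    d_ly = reference.ly - comparator.ly
    if abs(d_qaly) < 1e-12:
        dominance = "dominant" if d_cost < 0 else "dominated" if d_cost > 0 else "tradeoff"
        icer_q = icer_l = None
        if dominance == "tradeoff":
            icer_q = icer_l = 0.0
    elif d_cost >= 0 and d_qaly > 0 or d_cost <= 0 and d_qaly < 0:
        dominance = "tradeoff"
        icer_q = d_cost / d_qaly
        icer_l = d_cost / d_ly if abs(d_ly) > 1e-12 else None
    elif d_cost < 0 and d_qaly > 0:
        dominance = "dominant"
        icer_q = icer_l = None
    else:
        dominance = "dominated"
        icer_q = icer_l = None
    return CEResult(reference=reference, comparator=comparator,
                    d_cost=d_cost, d_qaly=d_qaly, d_ly=d_ly,
                    dominance=dominance, icer_qaly=icer_q, icer_ly=icer_l)


def evaluate_icer(params: ParameterSet) -> CEResult:
    """Both arms plus incremental analysis for one parameter set."""
    return compute_icer(evaluate_strategy(params, "testing"),
                        evaluate_strategy(params, "no_testing"))


# deterministic sensitivity analysis ----------------------------------------

@dataclass
class DSAScenario:
    name: str
    path: str
    low: float
    high: float
    mode: str = "set"                # "set" | "scale"
    icer_low: Optional[float] = None
    icer_high: Optional[float] = None

    @property
    def width(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return float("inf")      # dominance at a bound: widest bar
        return abs(self.icer_high - self.icer_low)


def _apply_bound(params: ParameterSet, path: str, value: float, mode: str) -> None:
    if mode == "set":
        set_path(params, path, value)
    elif mode == "scale":
        current = get_path(params, path)
        if isinstance(current, list):
            set_path_target = [x * value for x in current]
            keys = path.split(".")
            parent = params
            for k in keys[:-1]:
                parent = get_path(parent, k)
            setattr(parent, keys[-1], set_path_target)
        else:
            set_path(params, path, current * value)
    else:
        raise ValueError(f"unknown scenario mode {mode!r}")


def load_dsa_scenarios(path: Optional[str] = None) -> list[DSAScenario]:
    """Load the DSA scenario set (the packaged tornado set when path is None)."""
    if path is None:
        text = resources.files("hboc_cea").joinpath("data/dsa_scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [DSAScenario(name=e["name"], path=e["path"], low=float(e["low"]),
                        high=float(e["high"]), mode=e.get("mode", "set"))
            for e in raw["scenarios"]]


def run_dsa(params: ParameterSet, scenarios: Sequence[DSAScenario]) -> list[DSAScenario]:
    """One-way DSA over the scenario list; returns tornado-ordered results."""
    for sc in scenarios:
        get_path(params, sc.path)    # fail fast on unknown paths
    out: list[DSAScenario] = []
    for sc in scenarios:
        icers = []
        for bound in (sc.low, sc.high):
            trial = params.copy()
            _apply_bound(trial, sc.path, bound, sc.mode)
            icers.append(evaluate_icer(trial).icer_qaly)
        out.append(DSAScenario(name=sc.name, path=sc.path, low=sc.low, high=sc.high,
                               mode=sc.mode, icer_low=icers[0], icer_high=icers[1]))
    out.sort(key=lambda s: s.width, reverse=True)
    return out


# probabilistic sensitivity analysis ----------------------------------------

@dataclass
class PSAResult:
    n_samples: int
    seed: int
    d_cost: np.ndarray               # (n_samples,)
    d_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray                 # P(cost-effective) at each WTP
    inmb: np.ndarray                 # mean INMB at each WTP
    sampled_paths: list[str] = field(default_factory=list)


def _repair_cumulative(params: ParameterSet) -> None:
    """Independently sampled cumulative-mortality years may break monotonicity;
    restore it with a running maximum (documented repair, not resampling)."""
    for sched in (params.probabilities.metastatic_death, params.probabilities.oc_death):
        prev = 0.0
        for i, c in enumerate(sched.cum):
            c = min(max(c, prev), 1.0)
            sched.cum[i] = c
            prev = c


def _sanitize_draws(trial: ParameterSet) -> int:
    """Project extreme draws back onto the feasible simplex.

    Independent sampling can, rarely, give cause-specific annual risks whose
    sum exceeds 1 (e.g. the heavy-tailed well→OC beta); the engine treats
    that as a hard parameter error, so such draws are scaled down
    proportionally here.  Returns the number of constraint groups adjusted.
    """
    p = trial.probabilities
    fixed = 0
    limit = 1.0 - 1e-9

    def shrink(total: float, setters) -> int:
        nonlocal fixed
        if total > limit:
            f = limit / total
            for set_fn in setters:
                set_fn(f)
            fixed += 1
        return fixed

    bands = p.well_to_bc_carrier.bands
    top = max(b.p for b in bands)
    shrink(top + p.well_to_oc_carrier,
           [lambda f: [setattr(b, "p", b.p * f) for b in bands],
            lambda f: setattr(p, "well_to_oc_carrier", p.well_to_oc_carrier * f)])

    ps = p.post_surgery
    if hasattr(ps.bc_after_oophorectomy, "bands"):
        obands = ps.bc_after_oophorectomy.bands
        otop = max(b.p for b in obands)
        shrink(otop + ps.oc_after_oophorectomy,
               [lambda f: [setattr(b, "p", b.p * f) for b in obands],
                lambda f: setattr(ps, "oc_after_oophorectomy",
                                  ps.oc_after_oophorectomy * f)])

    for rec_attr in ("recurrence_bc_carrier", "recurrence_bc_noncarrier"):
        rec = getattr(p, rec_attr)
        total = rec + p.bc_to_metastatic + p.bc_to_oc + p.bc_mortality
        if total > limit:
            f = limit / total
            setattr(p, rec_attr, rec * f)
            p.bc_to_metastatic *= f
            p.bc_to_oc *= f
            p.bc_mortality *= f
            fixed += 1
    return fixed


def run_psa(params: ParameterSet, n_samples: int, seed: int,
            wtp_grid: Optional[np.ndarray] = None) -> PSAResult:
    """Monte Carlo PSA: draw parameters, re-run both arms per draw."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    wtp = np.asarray(wtp_grid if wtp_grid is not None else DEFAULT_WTP_GRID, dtype=float)
    rng = np.random.default_rng(seed)

    specs: list[UncertaintySpec] = params.uncertainty
    draws: dict[str, np.ndarray] = {}
    for spec in specs:
        mean = float(get_path(params, spec.path))
        if spec.family == "fixed" or mean == 0.0:
            continue
        dist = fit_distribution(mean, sd=spec.resolved_sd(mean), family=spec.family)
        draws[spec.path] = dist.sample(rng, n_samples)

    d_cost = np.empty(n_samples)
    d_qaly = np.empty(n_samples)
    for i in range(n_samples):
        trial = params.copy()
        for path, values in draws.items():
            set_path(trial, path, float(values[i]))
        if trial.probabilities.schedule_form == "cumulative":
            _repair_cumulative(trial)
        _sanitize_draws(trial)
        res = evaluate_icer(trial)
        d_cost[i] = res.d_cost
        d_qaly[i] = res.d_qaly

    nmb = wtp[:, None] * d_qaly[None, :] - d_cost[None, :]
    ceac = (nmb > 0).mean(axis=1)
    inmb = wtp * d_qaly.mean() - d_cost.mean()
    return PSAResult(n_samples=n_samples, seed=seed, d_cost=d_cost, d_qaly=d_qaly,
                     wtp_grid=wtp, ceac=ceac, inmb=inmb,
                     sampled_paths=sorted(draws))


def ceac_threshold(psa: PSAResult, p: float = 0.5) -> Optional[float]:
    """Smallest grid WTP at which the CEAC reaches probability ``p``.

    Returns None when the curve never crosses ``p`` on the grid ("above
    grid max").
    """
    idx = np.nonzero(psa.ceac >= p)[0]
    if len(idx) == 0:
        return None
    return float(psa.wtp_grid[idx[0]])
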