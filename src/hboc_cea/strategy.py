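"""Decision-tree expansion of the two compared strategies.

The testing arm splits the cohort by test result (18% positive) and, among
positives, by choice of risk-reducing option (mastectomy 3%, oophorectomy
12%, both 12%, intensified surveillance for the rest).  The no-testing arm
is the same population unaware of its mutation status: 18% carriers and 82%
non-carriers under standard care.  Every woman in the testing arm is charged
the per-woman genetic-test cost at cycle 0 — the test must be performed to
learn the result — and surgery branches are additionally charged their
operation at cycle 0.

Women diagnosed after a positive test use the cheaper "first- or
second-degree relative" breast-cancer treatment schedule (earlier-stage
diagnosis under intensified surveillance); negatives and the whole
no-testing arm use the "index" schedule.  Intensive screening is charged
while well to surveillance and oophorectomy-only branches (the breasts
remain at risk); mastectomy and both-surgery branches, negatives, and the
no-testing arm pay standard care.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .markov import Accrual, Subcohort, accumulate, run_trace
from .params import ParameterSet


@dataclass
class StrategyResult:
    arm: str
    cost: float
    qaly: float
    ly: float
    subcohorts: list[Subcohort] = field(default_factory=list)
    breakdown: dict[str, Accrual] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "cost": self.cost,
            "qaly": self.qaly,
            "ly": self.ly,
            "subcohorts": {
                s.name: {"weight": s.weight,
                         "cost": self.breakdown[s.name].cost,
                         "qaly": self.breakdown[s.name].qaly,
                         "ly": self.breakdown[s.name].ly}
                for s in self.subcohorts
            },
        }


def expand_arm(params: ParameterSet, arm: str) -> list[Subcohort]:
    """Weighted subcohorts for one arm of the decision tree."""
    p = params.probabilities
    c = params.costs
    pos = p.p_positive_test
    up = p.uptake
    if up.mastectomy + up.oophorectomy + up.both > 1.0 + 1e-12:
        raise ValueError("uptake probabilities sum to more than 1")
    test_cost = c.test_cost

    if arm == "testing":
        subs = [
            Subcohort(
                name="negative", arm=arm, weight=1.0 - pos, carrier=False,
                test_result="negative", prevention="standard_care",
                bc_rate=p.well_to_bc_noncarrier, oc_rate=p.well_to_oc_noncarrier,
                recurrence=p.recurrence_bc_noncarrier, utility_mode="negative",
                screening_cost=c.standard_care_annual, one_time_cost=test_cost,
                bc_cost_schedule="index"),
            Subcohort(
                name="positive_surveillance", arm=arm, weight=pos * up.surveillance,
                carrier=True, test_result="positive", prevention="surveillance",
                bc_rate=p.well_to_bc_carrier, oc_rate=p.well_to_oc_carrier,
                recurrence=p.recurrence_bc_carrier, utility_mode="surveillance",
                screening_cost=c.intensive_screening_annual, one_time_cost=test_cost,
                bc_cost_schedule="relative"),
            Subcohort(
                name="positive_mastectomy", arm=arm, weight=pos * up.mastectomy,
                carrier=True, test_result="positive", prevention="mastectomy",
                bc_rate=p.post_surgery.bc_after_mastectomy,
                oc_rate=p.post_surgery.oc_after_mastectomy,
                recurrence=p.recurrence_bc_carrier, utility_mode="mastectomy",
                screening_cost=c.standard_care_annual,
                one_time_cost=test_cost + c.surgery.mastectomy,
                bc_cost_schedule="relative"),
            Subcohort(
                name="positive_oophorectomy", arm=arm, weight=pos * up.oophorectomy,
                carrier=True, test_result="positive", prevention="oophorectomy",
                bc_rate=p.post_surgery.bc_after_oophorectomy,
                oc_rate=p.post_surgery.oc_after_oophorectomy,
                recurrence=p.recurrence_bc_carrier, utility_mode="oophorectomy",
                screening_cost=c.intensive_screening_annual,
                one_time_cost=test_cost + c.surgery.oophorectomy,
                bc_cost_schedule="relative"),
            Subcohort(
                name="positive_both", arm=arm, weight=pos * up.both,
                carrier=True, test_result="positive", prevention="both",
                bc_rate=p.post_surgery.bc_after_both,
                oc_rate=p.post_surgery.oc_after_both,
                recurrence=p.recurrence_bc_carrier, utility_mode="both",
                screening_cost=c.standard_care_annual,
                one_time_cost=test_cost + c.surgery.both,
                bc_cost_schedule="relative"),
        ]
    elif arm == "no_testing":
        subs = [
            Subcohort(
                name="untested_carrier", arm=arm, weight=pos, carrier=True,
                test_result="untested", prevention="standard_care",
                bc_rate=p.well_to_bc_carrier, oc_rate=p.well_to_oc_carrier,
                recurrence=p.recurrence_bc_carrier, utility_mode="untested",
                screening_cost=c.standard_care_annual, one_time_cost=0.0,
                bc_cost_schedule="index"),
            Subcohort(
                name="untested_noncarrier", arm=arm, weight=1.0 - pos, carrier=False,
                test_result="untested", prevention="standard_care",
                bc_rate=p.well_to_bc_noncarrier, oc_rate=p.well_to_oc_noncarrier,
                recurrence=p.recurrence_bc_noncarrier, utility_mode="untested",
                screening_cost=c.standard_care_annual, one_time_cost=0.0,
                bc_cost_schedule="index"),
        ]
    else:
        raise ValueError(f"unknown arm {arm!r}")

    subs = [s for s in subs if s.weight > 0.0]
    total = sum(s.weight for s in subs)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"arm {arm!r} weights sum to {total}, expected 1")
    return subs


def evaluate_strategy(params: ParameterSet, arm: str) -> StrategyResult:
    """Run the Markov engine for every subcohort and aggregate the arm."""
    subs = expand_arm(params, arm)
    breakdown: dict[str, Accrual] = {}
    cost = qaly = ly = 0.0
    for s in subs:
        acc = accumulate(run_trace(params, s), params, s)
        breakdown[s.name] = acc
        cost += s.weight * acc.cost
        qaly += s.weight * acc.qaly
        ly += s.weight * acc.ly
    return StrategyResult(arm=arm, cost=cost, qaly=qaly, ly=ly,
                          subcohorts=subs, breakdown=breakdown)
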