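"""Tunnel-expanded Markov cohort engine.

The cohort moves yearly among seven clinical states — well, non-metastatic
breast cancer (BC), metastatic BC, ovarian cancer (OC), post-BC, post-OC and
death — expanded with five-year tunnel states so that mortality, costs and
utilities can depend on time since diagnosis:

* BC chain: ``bc`` (year 1), ``post_bc_y2..y5``, ``post_bc`` (year 6 on).
  Every year the chain is exposed to contralateral BC (which resets the
  clock to ``bc`` and re-charges the first-year treatment cost), metastasis,
  ovarian cancer, cause-specific BC mortality, and background mortality.
* Metastatic chain: ``met_y1..y5`` then ``met`` — a terminal tunnel whose
  per-year death probabilities come from the cumulative five-year KM
  schedule; the year-5 conditional probability holds from year 6 on.
* OC chain: ``oc`` (year 1), ``post_oc_y2..y5``, ``post_oc``; deaths follow
  the OC KM schedule; from year 6 on only background mortality applies.

Background all-cause mortality applies additively inside cancer states on
top of the cause-specific schedules.  When the combined outflow of a row
would exceed 1 (which the shipped life table forces at ages >= 85, where the
annual all-cause probability is 1.0), death takes priority and the remaining
exits are scaled into the leftover mass; the number of capped cells is
reported on the trace.  A genuine parameter pathology — cause-specific exits
alone exceeding 1 — raises an error naming the state and cycle.

No half-cycle correction is applied: state membership is evaluated at cycle
start, and each of the 70 cycles accrues one year of costs, utility and life
lived in that state, discounted at ``(1+r)^-t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import AgeBandedRate, ParameterSet, conditional_schedule

# state indexing ------------------------------------------------------------

STATES: tuple[str, ...] = (
    "well",
    "bc", "post_bc_y2", "post_bc_y3", "post_bc_y4", "post_bc_y5", "post_bc",
    "met_y1", "met_y2", "met_y3", "met_y4", "met_y5", "met",
    "oc", "post_oc_y2", "post_oc_y3", "post_oc_y4", "post_oc_y5", "post_oc",
    "death",
)
IDX = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)

WELL = IDX["well"]
BC1 = IDX["bc"]
BC_CHAIN = [IDX[s] for s in ("bc", "post_bc_y2", "post_bc_y3", "post_bc_y4",
                             "post_bc_y5", "post_bc")]
MET1 = IDX["met_y1"]
MET_CHAIN = [IDX[s] for s in ("met_y1", "met_y2", "met_y3", "met_y4", "met_y5", "met")]
OC1 = IDX["oc"]
OC_CHAIN = [IDX[s] for s in ("oc", "post_oc_y2", "post_oc_y3", "post_oc_y4",
                             "post_oc_y5", "post_oc")]
DEATH = IDX["death"]


@dataclass
class Subcohort:
    """One homogeneous branch of a strategy arm.

    Carries everything the engine needs: the well-state incidence sources,
    which treatment-cost schedule applies, the well-state utility mode, the
    annual screening cost while well, and one-time cycle-0 costs (genetic
    test and, for surgery branches, the prophylactic operation).
    """

    name: str
    arm: str                         # "testing" | "no_testing"
    weight: float
    carrier: bool
    test_result: str                 # "positive" | "negative" | "untested"
    prevention: str                  # "surveillance" | "mastectomy" | "oophorectomy"
    #                                  | "both" | "standard_care"
    bc_rate: AgeBandedRate | float = 0.0
    oc_rate: float = 0.0
    recurrence: float = 0.0
    utility_mode: str = "untested"   # "negative" | "untested" | "surveillance"
    #                                  | "mastectomy" | "oophorectomy" | "both"
    screening_cost: float = 0.0
    one_time_cost: float = 0.0
    bc_cost_schedule: str = "index"  # "index" | "relative"


@dataclass
class CohortTrace:
    """State-occupancy proportions per cycle plus engine diagnostics."""

    occupancy: np.ndarray            # (horizon + 1, N_STATES)
    capped_cells: int = 0            # rows where outflow was death-capped
    matrices: Optional[np.ndarray] = None  # (horizon, N_STATES, N_STATES)


@dataclass
class Accrual:
    cost: float
    qaly: float
    ly: float
    utility_clamped: int = 0


# transition matrices -------------------------------------------------------

def _rate_array(rate: AgeBandedRate | float, start_age: int, horizon: int) -> np.ndarray:
    if isinstance(rate, AgeBandedRate):
        return rate.as_array(start_age, horizon)
    return np.full(horizon, float(rate))


def transition_matrices(params: ParameterSet, sub: Subcohort) -> tuple[np.ndarray, int]:
    """All per-cycle transition matrices for one subcohort.

    Returns ``(P, capped)`` where ``P`` has shape (horizon, n_states,
    n_states) and ``capped`` counts state-cycle cells where background
    mortality forced death-priority scaling of the competing exits.
    """
    p = params.probabilities
    H = params.model.horizon_years
    start = params.model.start_age

    q = _rate_array(p.all_cause_mortality, start, H)          # background death
    p_bc = _rate_array(sub.bc_rate, start, H)                 # well -> BC
    p_oc = np.full(H, sub.oc_rate)                            # well -> OC

    rec = sub.recurrence
    met = p.bc_to_metastatic
    bcoc = p.bc_to_oc
    bcd = p.bc_mortality
    cond_met = conditional_schedule(p.metastatic_death, p.schedule_form)
    cond_oc = conditional_schedule(p.oc_death, p.schedule_form)

    P = np.zeros((H, N_STATES, N_STATES))
    capped = 0

    # well row: cancer incidence and background death, additive
    s = p_bc + p_oc
    if np.any(p_bc + p_oc > 1.0 + 1e-12):
        t = int(np.argmax(p_bc + p_oc > 1.0 + 1e-12))
        raise ValueError(f"state 'well', cycle {t}: cancer exits sum to "
                         f"{(p_bc + p_oc)[t]:.4f} > 1")
    rem = 1.0 - q
    scale = np.where(s > rem, np.divide(rem, s, out=np.ones_like(s), where=s > 0), 1.0)
    scale = np.clip(scale, 0.0, 1.0)
    capped += int(np.sum(scale < 1.0))
    P[:, WELL, BC1] = p_bc * scale
    P[:, WELL, OC1] = p_oc * scale
    P[:, WELL, DEATH] = q
    P[:, WELL, WELL] = 1.0 - q - (p_bc + p_oc) * scale

    # BC / post-BC chain
    specific = rec + met + bcoc + bcd
    if specific > 1.0 + 1e-12:
        raise ValueError(f"BC-chain cause-specific exits sum to {specific:.4f} > 1")
    for j, st in enumerate(BC_CHAIN):
        nxt = BC_CHAIN[min(j + 1, len(BC_CHAIN) - 1)]
        d = np.minimum(1.0, q + bcd)
        rem = 1.0 - d
        s_other = rec + met + bcoc
        if s_other > 0:
            sc = np.clip(rem / s_other, 0.0, 1.0)
        else:
            sc = np.ones(H)
        capped += int(np.sum((sc < 1.0) | (q + bcd > 1.0)))
        P[:, st, BC1] += rec * sc
        P[:, st, MET1] += met * sc
        P[:, st, OC1] += bcoc * sc
        P[:, st, DEATH] += d
        P[:, st, nxt] += 1.0 - d - s_other * sc

    # metastatic chain: terminal, conditional KM schedule + background death
    for j, st in enumerate(MET_CHAIN):
        nxt = MET_CHAIN[min(j + 1, len(MET_CHAIN) - 1)]
        c = cond_met.at_year(j + 1) if j < 5 else cond_met.tail
        d = np.minimum(1.0, q + c)
        capped += int(np.sum(q + c > 1.0))
        P[:, st, DEATH] += d
        P[:, st, nxt] += 1.0 - d

    # OC chain: conditional KM schedule + background death; year 6 on only background
    for j, st in enumerate(OC_CHAIN):
        nxt = OC_CHAIN[min(j + 1, len(OC_CHAIN) - 1)]
        c = cond_oc.at_year(j + 1) if j < 5 else cond_oc.tail
        d = np.minimum(1.0, q + c)
        capped += int(np.sum(q + c > 1.0))
        P[:, st, DEATH] += d
        P[:, st, nxt] += 1.0 - d

    P[:, DEATH, DEATH] = 1.0
    return P, capped


def build_transition_matrix(params: ParameterSet, sub: Subcohort,
                            cycle: int) -> np.ndarray:
    """Row-stochastic transition matrix for one cycle of one subcohort."""
    H = params.model.horizon_years
    if not 0 <= cycle < H:
        raise ValueError(f"cycle {cycle} outside 0..{H - 1}")
    P, _ = transition_matrices(params, sub)
    return P[cycle]


def run_trace(params: ParameterSet, sub: Subcohort,
              keep_matrices: bool = False) -> CohortTrace:
    """Propagate a unit cohort (all mass in 'well') through all cycles."""
    H = params.model.horizon_years
    P, capped = transition_matrices(params, sub)
    occ = np.zeros((H + 1, N_STATES))
    occ[0, WELL] = 1.0
    for t in range(H):
        occ[t + 1] = occ[t] @ P[t]
    return CohortTrace(occupancy=occ, capped_cells=capped,
                       matrices=P if keep_matrices else None)


# accrual -------------------------------------------------------------------

def utility_matrix(params: ParameterSet, sub: Subcohort) -> tuple[np.ndarray, int]:
    """Per-cycle, per-state utility weights; returns (U, clamp_count).

    Utilities are the age-declining baseline ``0.920 - 0.00029*(age-30)``
    times a state multiplier.  States with recovery climb linearly from the
    year-1 value by their increment over tunnel years 2-5, then hold the
    steady post-state multiplier.  Negative values are clamped to 0 and
    counted (the base case must produce none).
    """
    u = params.utilities
    H = params.model.horizon_years
    b = u.baseline_age30 - u.annual_age_decrement * np.arange(H)

    U = np.zeros((H, N_STATES))

    # well state: depends on what the woman knows / chose at cycle 0
    mode = sub.utility_mode
    if mode == "negative":
        U[:, WELL] = u.multiplier_negative * b
    elif mode == "untested":
        U[:, WELL] = u.multiplier_untested * b
    elif mode == "surveillance":
        U[:, WELL] = u.multiplier_high_risk * b
    elif mode in ("mastectomy", "oophorectomy", "both"):
        su = getattr(u, mode)
        well = u.multiplier_high_risk * b.copy()
        for t in range(min(5, H)):  # surgery at cycle 0; tunnel year = t + 1
            well[t] = su.multiplier * b[t] + su.recovery_increment * t
        U[:, WELL] = well
    else:
        raise ValueError(f"unknown utility mode {mode!r}")

    # BC chain: year 1 at the BC multiplier, recovery through year 5,
    # steady post-BC multiplier afterwards
    for j, st in enumerate(BC_CHAIN):
        if j < 5:
            U[:, st] = u.bc.multiplier * b + u.bc.recovery_increment * j
        else:
            U[:, st] = u.bc.post_multiplier * b

    for st in MET_CHAIN:
        U[:, st] = u.metastatic * b

    for j, st in enumerate(OC_CHAIN):
        if j < 5:
            U[:, st] = u.oc.multiplier * b + u.oc.recovery_increment * j
        else:
            U[:, st] = u.oc.post_multiplier * b

    U[:, DEATH] = 0.0
    clamped = int(np.sum(U < 0))
    np.clip(U, 0.0, 1.0, out=U)
    return U, clamped


def cost_matrix(params: ParameterSet, sub: Subcohort) -> np.ndarray:
    """Per-cycle, per-state annual cost accruals (excludes one-time costs)."""
    c = params.costs
    H = params.model.horizon_years
    C = np.zeros((H, N_STATES))
    C[:, WELL] = sub.screening_cost
    bc_sched = c.bc_relative_yearly if sub.bc_cost_schedule == "relative" \
        else c.bc_index_yearly
    for j, st in enumerate(BC_CHAIN):
        C[:, st] = bc_sched[j] if j < 5 else bc_sched[4]
    for j, st in enumerate(MET_CHAIN):
        C[:, st] = c.metastatic_yearly[j] if j < 5 else c.metastatic_yearly[4]
    for j, st in enumerate(OC_CHAIN):
        C[:, st] = c.oc_yearly[j] if j < 5 else c.oc_yearly[4]
    C[:, DEATH] = 0.0
    return C


def accumulate(trace: CohortTrace, params: ParameterSet, sub: Subcohort) -> Accrual:
    """Discounted totals for one subcohort: cost, QALYs and life years.

    One-time costs (genetic test, prophylactic surgery) are charged at cycle
    0, undiscounted; annual accruals use start-of-cycle state membership.
    """
    H = params.model.horizon_years
    r = params.model.discount_rate
    disc = (1.0 + r) ** -np.arange(H)
    occ = trace.occupancy[:H]

    U, clamped = utility_matrix(params, sub)
    C = cost_matrix(params, sub)
    alive = np.ones(N_STATES)
    alive[DEATH] = 0.0

    cost = float(np.sum(disc * np.einsum("ts,ts->t", occ, C))) + sub.one_time_cost
    qaly = float(np.sum(disc * np.einsum("ts,ts->t", occ, U)))
    ly = float(np.sum(disc * (occ @ alive)))
    return Accrual(cost=cost, qaly=qaly, ly=ly, utility_clamped=clamped)
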