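"""Synthetic time-to-event registry and Kaplan-Meier parameter derivation.

The transition probabilities of the model were derived from a hospital
registry of women tested for BRCA1/2 germline variants (2,307 women tested
2011-2020: 275 carrier index cases, 1,269 non-carrier index cases, 356
carrier relatives, 407 non-carrier relatives), via Kaplan-Meier estimation
with a separate eligible-at-baseline group per transition.  That extract is
not deposited, so this module generates individual-level records with the
same statistical structure — per-subject exponential event times discretised
to annual probabilities, competing events censored at their event time
(naive KM, mirroring the source analysis), uniform entry over the follow-up
window — and re-derives annual transition probabilities from them.  The
round trip (ProbabilityBlock -> cohort -> KM -> annual probabilities) is the
parameter-recovery test bench.

Product-limit estimation is delegated to lifelines; Greenwood variance and
the annualised band probabilities p = 1 - S(t+1)/S(t) are computed from its
event table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .params import ProbabilityBlock, cumulative_to_conditional

_CSV_COLUMNS = ["subject_id", "group", "carrier", "prophylaxis", "entry_age",
                "event", "time_to_event"]


@dataclass
class EventRecord:
    subject_id: int
    group: str                 # "index" | "relative"
    carrier: bool
    prophylaxis: str           # "none" | "mastectomy" | "oophorectomy" | "both"
    entry_age: float
    event: str                 # "BC" | "OC" | "contralateral_BC" | "metastasis"
    #                            | "death" | "censored"
    time_to_event: float       # years from entry

    def __post_init__(self) -> None:
        if self.time_to_event < 0:
            raise ValueError("time_to_event must be >= 0")
        if self.prophylaxis != "none" and not self.carrier:
            raise ValueError("prophylaxis recorded for a non-carrier")


@dataclass
class SyntheticCohortSpec:
    """Registry-shaped simulation settings; defaults mirror the source cohort."""

    n_index_carriers: int = 275
    n_index_noncarriers: int = 1269
    n_relative_carriers: int = 356
    n_relative_noncarriers: int = 407
    rates: Optional[ProbabilityBlock] = None   # defaults to the shipped base case
    censoring_rate: float = 0.03               # annual loss to follow-up
    followup_years: float = 9.0                # 2011-2020 window, uniform entry
    entry_age_range: tuple[int, int] = (30, 55)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_index_carriers", "n_index_noncarriers",
                     "n_relative_carriers", "n_relative_noncarriers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0,1)")


def _default_rates() -> ProbabilityBlock:
    from .params import load_parameters
    return load_parameters().probabilities


def _annual_to_hazard(p: float) -> float:
    if p >= 1.0:
        return math.inf
    return -math.log(1.0 - p)


def _draw_competing(rng: np.random.Generator, yearly: Sequence[dict[str, float]],
                    followup: float, censor_rate: float) -> tuple[str, float]:
    """Piecewise-exponential competing events, one record per subject.

    ``yearly[y]`` maps event name -> annual probability during year ``y``
    (the last entry repeats).  Returns (event, time) with administrative
    censoring at ``followup`` and exponential loss to follow-up.
    """
    censor_t = math.inf
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / _annual_to_hazard(censor_rate))
    t_end = min(followup, censor_t)
    y = 0
    while y < t_end:
        probs = yearly[min(y, len(yearly) - 1)]
        names = list(probs)
        lam = np.array([_annual_to_hazard(probs[n]) for n in names])
        total = lam.sum()
        if total <= 0:
            y += 1
            continue
        if math.isinf(total):
            # certain event this year; pick among the certain causes
            certain = [n for n, l in zip(names, lam) if math.isinf(l)]
            t = y + rng.uniform(0.0, min(1.0, t_end - y))
            if t >= t_end:
                break
            return str(rng.choice(certain)), t
        wait = rng.exponential(1.0 / total)
        if wait < 1.0 and y + wait < t_end:
            name = names[int(rng.choice(len(names), p=lam / total))]
            return name, y + wait
        y += 1
    return "censored", t_end


def simulate_cohort(spec: SyntheticCohortSpec,
                    rng: Optional[np.random.Generator] = None) -> list[EventRecord]:
    """Generate one synthetic registry extract; deterministic given the seed."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rates = spec.rates if spec.rates is not None else _default_rates()
    up = rates.uptake
    records: list[EventRecord] = []
    sid = 0
    groups = ([("index", True)] * spec.n_index_carriers
              + [("index", False)] * spec.n_index_noncarriers
              + [("relative", True)] * spec.n_relative_carriers
              + [("relative", False)] * spec.n_relative_noncarriers)
    lo, hi = spec.entry_age_range
    for group, carrier in groups:
        entry_age = int(rng.integers(lo, hi + 1))
        prophylaxis = "none"
        if carrier:
            u = rng.uniform()
            if u < up.mastectomy:
                prophylaxis = "mastectomy"
            elif u < up.mastectomy + up.oophorectomy:
                prophylaxis = "oophorectomy"
            elif u < up.mastectomy + up.oophorectomy + up.both:
                prophylaxis = "both"
        followup = rng.uniform(0.0, spec.followup_years)

        def p_bc(age: float) -> float:
            ps = rates.post_surgery
            if prophylaxis == "mastectomy":
                return float(ps.bc_after_mastectomy)
            if prophylaxis == "both":
                return float(ps.bc_after_both)
            if prophylaxis == "oophorectomy":
                r = ps.bc_after_oophorectomy
                return r.lookup(age) if hasattr(r, "lookup") else float(r)
            src = rates.well_to_bc_carrier if carrier else rates.well_to_bc_noncarrier
            return src.lookup(age)

        def p_oc() -> float:
            ps = rates.post_surgery
            if prophylaxis == "mastectomy":
                return float(ps.oc_after_mastectomy)
            if prophylaxis == "both":
                return float(ps.oc_after_both)
            if prophylaxis == "oophorectomy":
                return float(ps.oc_after_oophorectomy)
            return rates.well_to_oc_carrier if carrier else rates.well_to_oc_noncarrier

        yearly = [{"BC": p_bc(entry_age + y), "OC": p_oc(),
                   "death": rates.all_cause_mortality.lookup(
                       min(entry_age + y, 100))}
                  for y in range(int(math.ceil(spec.followup_years)) + 1)]
        event, t = _draw_competing(rng, yearly, followup, spec.censoring_rate)
        records.append(EventRecord(subject_id=sid, group=group, carrier=carrier,
                                   prophylaxis=prophylaxis, entry_age=entry_age,
                                   event=event, time_to_event=round(t, 2)))
        sid += 1
    return records


def records_to_frame(records: Iterable[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _CSV_COLUMNS} for r in records])


def records_to_csv(records: Iterable[EventRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_csv(path: str) -> list[EventRecord]:
    df = pd.read_csv(path)
    return [EventRecord(subject_id=int(r.subject_id), group=str(r.group),
                        carrier=bool(r.carrier), prophylaxis=str(r.prophylaxis),
                        entry_age=float(r.entry_age), event=str(r.event),
                        time_to_event=float(r.time_to_event))
            for r in df.itertuples()]


# Kaplan-Meier --------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and risk-set sizes."""

    times: np.ndarray            # event times (including censor times)
    survival: np.ndarray         # S(t) at each time (right-continuous step)
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_var: np.ndarray    # Var[S(t)] at each time

    @property
    def max_time(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def var_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    def log_ratio_var(self, t0: float, t1: float) -> float:
        """Var[log(S(t1)/S(t0))] by summing Greenwood increments d/(n(n-d))."""
        mask = (self.times > t0) & (self.times <= t1) & (self.n_events > 0)
        n = self.at_risk[mask]
        d = self.n_events[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = d / (n * (n - d))
        return float(np.sum(terms[np.isfinite(terms)]))


def km_estimate(records: Sequence[EventRecord], event_of_interest: str,
                stratum: Optional[dict] = None) -> KMCurve:
    """Naive Kaplan-Meier for one event type within a stratum.

    Subjects whose record shows a different (competing) event are censored
    at their event time, mirroring the single-event KM analysis the
    transition probabilities were originally derived with.  ``stratum``
    filters on EventRecord fields, e.g. ``{"carrier": True}``.
    """
    rows = list(records)
    if stratum:
        rows = [r for r in rows if all(getattr(r, k) == v for k, v in stratum.items())]
    if not rows:
        raise ValueError(f"empty stratum: {stratum!r}")
    rows.sort(key=lambda r: r.subject_id)
    T = np.array([r.time_to_event for r in rows])
    E = np.array([r.event == event_of_interest for r in rows], dtype=int)

    kmf = KaplanMeierFitter()
    kmf.fit(T, E)
    table = kmf.event_table.iloc[1:] if 0.0 not in T else kmf.event_table
    times = kmf.event_table.index.to_numpy(dtype=float)
    # align survival with the event-table timeline
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    d = kmf.event_table["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    greenwood = surv**2 * np.cumsum(incr)
    keep = times > 0
    return KMCurve(times=times[keep], survival=surv[keep], at_risk=at_risk[keep],
                   n_events=d[keep], greenwood_var=greenwood[keep])


def annual_probability(curve: KMCurve, band: tuple[float, float]) -> float:
    """Band-averaged annual transition probability from a KM curve.

    For each whole year ``y`` in [lo, hi): p_y = 1 - S(y+1)/S(y); the band
    value is the mean over those years.
    """
    lo, hi = band
    if hi > curve.max_time + 1e-9:
        raise ValueError(f"band {band} extends beyond follow-up ({curve.max_time:.2f} y)")
    ps = []
    for y in range(int(lo), int(hi)):
        s0 = curve.survival_at(float(y))
        s1 = curve.survival_at(float(y + 1))
        if s0 <= 0:
            break
        ps.append(1.0 - s1 / s0)
    if not ps:
        raise ValueError(f"no usable years in band {band}")
    return float(np.mean(ps))


def annual_probability_ci(curve: KMCurve, band: tuple[float, float],
                          z: float = 1.96) -> tuple[float, float, float]:
    """Annualised probability over a band with a Greenwood 95% CI.

    Uses p = 1 - (S(hi)/S(lo))^(1/k) with the CI built on log(S(hi)/S(lo)).
    """
    lo, hi = band
    k = hi - lo
    s0, s1 = curve.survival_at(lo), curve.survival_at(hi)
    if s0 <= 0 or s1 <= 0:
        raise ValueError("survival reaches 0 inside the band")
    ratio = s1 / s0
    est = 1.0 - ratio ** (1.0 / k)
    se = math.sqrt(max(curve.log_ratio_var(lo, hi), 0.0))
    log_lo, log_hi = math.log(ratio) - z * se, math.log(ratio) + z * se
    p_hi = 1.0 - math.exp(log_lo / k)
    p_lo = 1.0 - math.exp(log_hi / k)
    return est, max(p_lo, 0.0), min(p_hi, 1.0)


# parameter recovery --------------------------------------------------------

def _single_rate_stratum(rng: np.random.Generator, n: int,
                         hazards: dict[str, float], followup: float,
                         censor_rate: float) -> list[EventRecord]:
    recs = []
    for i in range(n):
        event, t = _draw_competing(rng, [hazards], followup, censor_rate)
        recs.append(EventRecord(subject_id=i, group="relative", carrier=True,
                                prophylaxis="none", entry_age=30.0,
                                event=event, time_to_event=t))
    return recs


def recovery_report(rates: ProbabilityBlock, n_per_stratum: int = 5000,
                    seed: int = 0, censor_rate: float = 0.03) -> pd.DataFrame:
    """Simulate -> KM-estimate -> compare, one row per recovered parameter.

    Each transition gets its own eligible-at-baseline stratum, as in the
    source analysis: well->BC per carrier age band, well->OC, contralateral
    recurrence, the five-year metastatic mortality schedule, and the
    prophylaxis uptake split.  Columns: parameter, truth, estimate, lo, hi,
    covered (truth inside the 95% CI).
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(name: str, truth: float, est: float, lo: float, hi: float) -> None:
        rows.append({"parameter": name, "truth": truth, "estimate": est,
                     "lo": lo, "hi": hi, "covered": lo <= truth <= hi})

    # carrier well->BC per age band (constant hazard within band, 5-year window)
    for band in rates.well_to_bc_carrier.bands:
        q = rates.all_cause_mortality.lookup(band.lo)
        recs = _single_rate_stratum(
            rng, n_per_stratum,
            {"BC": band.p, "OC": rates.well_to_oc_carrier, "death": q},
            followup=5.0, censor_rate=censor_rate)
        curve = km_estimate(recs, "BC")
        est, lo, hi = annual_probability_ci(curve, (0.0, 5.0))
        add(f"well_to_bc_carrier[{band.lo}]", band.p, est, lo, hi)

    # carrier well->OC
    recs = _single_rate_stratum(
        rng, n_per_stratum,
        {"OC": rates.well_to_oc_carrier,
         "BC": rates.well_to_bc_carrier.bands[0].p,
         "death": rates.all_cause_mortality.lookup(30)},
        followup=5.0, censor_rate=censor_rate)
    est, lo, hi = annual_probability_ci(km_estimate(recs, "OC"), (0.0, 5.0))
    add("well_to_oc_carrier", rates.well_to_oc_carrier, est, lo, hi)

    # contralateral recurrence among carriers with breast cancer
    recs = _single_rate_stratum(
        rng, n_per_stratum,
        {"contralateral_BC": rates.recurrence_bc_carrier,
         "metastasis": rates.bc_to_metastatic, "OC": rates.bc_to_oc,
         "death": rates.bc_mortality + rates.all_cause_mortality.lookup(30)},
        followup=5.0, censor_rate=censor_rate)
    est, lo, hi = annual_probability_ci(km_estimate(recs, "contralateral_BC"), (0.0, 5.0))
    add("recurrence_bc_carrier", rates.recurrence_bc_carrier, est, lo, hi)

    # metastatic five-year cumulative mortality
    cond = cumulative_to_conditional(rates.metastatic_death)
    yearly = [{"death": c} for c in cond.cond]
    recs = []
    for i in range(n_per_stratum):
        event, t = _draw_competing(rng, yearly, followup=5.0, censor_rate=censor_rate)
        recs.append(EventRecord(subject_id=i, group="index", carrier=True,
                                prophylaxis="none", entry_age=30.0,
                                event=event, time_to_event=t))
    curve = km_estimate(recs, "death")
    for j, cum_true in enumerate(rates.metastatic_death.cum, start=1):
        s = curve.survival_at(float(j))
        se = math.sqrt(max(curve.var_at(float(j)), 0.0))
        add(f"metastatic_death_cum[y{j}]", cum_true, 1.0 - s,
            1.0 - (s + 1.96 * se), 1.0 - (s - 1.96 * se))

    # uptake of risk-reducing options among carrier relatives
    up = rates.uptake
    draws = rng.uniform(size=n_per_stratum)
    counts = {
        "mastectomy": int(np.sum(draws < up.mastectomy)),
        "oophorectomy": int(np.sum((draws >= up.mastectomy)
                                   & (draws < up.mastectomy + up.oophorectomy))),
        "both": int(np.sum((draws >= up.mastectomy + up.oophorectomy)
                           & (draws < up.mastectomy + up.oophorectomy + up.both))),
    }
    for name, truth in (("mastectomy", up.mastectomy),
                        ("oophorectomy", up.oophorectomy), ("both", up.both)):
        phat = counts[name] / n_per_stratum
        se = math.sqrt(phat * (1.0 - phat) / n_per_stratum)
        add(f"uptake.{name}", truth, phat, phat - 1.96 * se, phat + 1.96 * se)

    return pd.DataFrame(rows)
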