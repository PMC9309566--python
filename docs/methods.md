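# Methods

## Model structure

The model is a deterministic Markov cohort simulation with 1-year cycles,
a 70-year horizon (ages 30–100), and costs and effects discounted at 5%
per year.  The seven clinical states are expanded into 20 engine states:

* `well`
* breast-cancer chain: `bc` (first year after diagnosis), `post_bc_y2..y5`
  (tunnel years), `post_bc` (steady state, year 6 on)
* metastatic chain: `met_y1..y5`, `met` (steady)
* ovarian-cancer chain: `oc`, `post_oc_y2..y5`, `post_oc`
* `death` (absorbing)

Transitions per cycle:

* From `well`: breast-cancer incidence (age-banded, by carrier status and
  prophylaxis), ovarian-cancer incidence, and background all-cause
  mortality, applied additively; the remainder stays well.
* From every BC-chain state: contralateral breast cancer (returns to `bc`,
  resetting the tunnel clock and re-charging the first-year treatment
  cost), metastasis (0.0134/yr), ovarian cancer (0.007/yr), cause-specific
  BC mortality (0.006/yr) plus background mortality; the remainder
  advances one tunnel year.
* The metastatic chain is terminal: per-year death probabilities from the
  five-year schedule, with the year-5 value held constant afterwards.
* The OC chain uses its five-year schedule; from year 6 on survivors sit
  in `post_oc` with background mortality only.
* Ovarian-to-breast transitions are excluded.

No half-cycle correction is applied; state membership is evaluated at
cycle start and each cycle accrues one year of cost, utility and life.
This overstates occupancy of the state of origin by up to half a cycle and
is listed under limitations.

### Mortality-schedule reading (`probabilities.schedule_form`)

The five-year mortality tables for metastatic breast cancer
(0.37, 0.61, 0.76, 0.85, 0.90) and ovarian cancer
(0.10, 0.18, 0.25, 0.32, 0.39) are stored verbatim and can be read two
ways:

* **conditional** (default): the printed values are per-cycle tunnel
  probabilities, the way annual tunnel tables are entered in cohort-model
  software.  Ovarian cancer then kills 77% within five years, matching its
  described lethality (roughly seven deaths per ten cases).
* **cumulative**: the printed values are cumulative Kaplan–Meier
  incidence; `cumulative_to_conditional` converts them with
  `cond[t] = (cum[t] − cum[t−1]) / (1 − cum[t−1])`, which round-trips to
  1e-12 and is property-tested.  Under this reading five-year OC mortality
  is 39%.

Both readings are one `--set probabilities.schedule_form=...` apart; all
structural tests pass under either.

### Outflow capping

The published life table assigns annual all-cause mortality 1.0 at ages
≥ 85, so from cycle 55 the nominal exits of several rows sum above 1.
Death takes priority: it keeps its full probability and the competing
exits are scaled into the remaining mass (the number of capped cells is
reported on the trace).  A `ValueError` naming the state and cycle is
raised only when the cause-specific exits alone exceed 1, which indicates
a genuinely infeasible parameter set rather than an old-age artefact.

## Utilities

Utility is `baseline(age) × multiplier`, with
`baseline(age) = 0.920 − 0.00029·(age − 30)` and multipliers by state and
tunnel year.  States with recovery climb linearly from their first-year
value by a fixed yearly increment over tunnel years 2–5 and hold the
steady post-state multiplier from year 6: breast cancer 0.77 → post-BC
0.79 (+0.0021/yr), ovarian cancer 0.34 → post-OC 0.83 (+0.111/yr),
prophylactic surgery 0.88 / 0.95 / 0.83 (mastectomy / oophorectomy /
both) → the well utility of a high-risk woman (+0.008, +0.0115, +0.02 per
year; the oophorectomy increment is not published and is derived as
(1 − 0.95)·0.920/4, mirroring the published pattern).  Metastatic disease
is 0.64 throughout; death is 0.

The published high-risk well utility (0.92, EQ-5D) is numerically the
same value as the age-30 baseline (0.920), so in the base case neither
awareness of high-risk status nor a negative test result changes
well-state utility; the engine retains the multiplier mechanism
(`utilities.multiplier_high_risk`) so a genuine decrement can be explored
— setting it to 0.92 reproduces the 0.920·0.92 = 0.8464 chain and makes
the testing strategy lose QALYs overall, because the 13% of the cohort
under lifelong surveillance then carries a permanent 8% utility penalty
that dwarfs the prevention gains.

Negative utilities after decrements would be clamped to 0 and counted;
the base case produces zero clamps (asserted in tests).

## Costs

All costs are 2021 R$ (SUS reimbursement values), accrued annually by
state: treatment schedules over tunnel years 1–5 with the year-5 value in
the steady states (BC index R$ 17,813.11 first year; BC
relatives-of-tested R$ 16,540.09; metastatic R$ 18,392.61 …; OC
R$ 14,224.92 …), intensive screening R$ 428.85/yr or standard care
R$ 55/yr while well, and one-time cycle-0 charges for the genetic test
and prophylactic surgery (R$ 3,484.26 / 621.00 / 4,105.26).

The genetic test is priced per family: one index test (R$ 1,800) plus
`n` relative tests (R$ 235), averaged per woman as
`(1800 + n·235)/n` — R$ 1,135 at the default `n = 2`.  Every woman in the
testing arm is charged it, negatives included.

Cost-schedule assignment: cancers diagnosed after a positive test use the
cheaper relatives schedule (earlier-stage diagnosis under surveillance);
negatives and the entire no-testing arm use the index schedule.
Intensive screening is charged while well to the surveillance and
oophorectomy-only groups (the breasts remain at risk); mastectomy-only
and both-surgery groups, negatives and untested women pay standard care.
These assignments are design choices where the source material is silent,
and each is a config knob.

## Strategy arms

Testing arm: negatives (0.82), positive-surveillance (0.18·0.73),
positive-mastectomy (0.18·0.03), positive-oophorectomy (0.18·0.12),
positive-both (0.18·0.12).  No-testing arm: untested carriers (0.18) and
non-carriers (0.82) under standard care.  Weights are validated to sum to
1 per arm; surgery occurs at cycle 0.  Post-surgery risks: mastectomy and
both-surgeries zero breast and ovarian risk; oophorectomy keeps
carrier-level breast risk (first band 0.014) and residual ovarian risk
0.01.

## Sensitivity analyses

The DSA clones the base parameters per scenario bound (the base case is
never mutated), re-runs both arms, and orders scenarios by
|ICER_high − ICER_low|.  The shipped set covers the discount rate
(0/0.10), breast-cancer risk after both surgeries (0/0.08), relatives
tested per index (4/1), ovarian-cancer risk after oophorectomy
(0.004/0.03), untested-group breast-cancer treatment costs (×0.6/×1.4),
the first oophorectomy breast-risk band, carrier contralateral recurrence,
and the metastasis rate (published CIs where available).

The PSA draws all registered uncertain parameters independently per
sample: beta for probabilities and utilities (method-of-moments from the
printed sd, or from a 95% CI via sd = (hi − lo)/3.92), gamma for costs
with a 40% coefficient of variation.  An infeasible beta sd is shrunk to
0.999 of the feasibility bound with a warning.  Two repairs keep sampled
parameter sets feasible: under the cumulative schedule reading,
independently sampled cumulative years are made monotone by running
maximum; and draws whose cause-specific annual risks sum above 1 (a rare
tail event of the heavily skewed well→OC beta, mean 0.013, sd 0.052) are
scaled back onto the simplex.  CEAC and INMB are evaluated on a WTP grid
of R$ 0–150,000 in steps of 500.  All randomness flows from a single
`numpy` generator per run, seeded explicitly.

## Synthetic registry and Kaplan–Meier derivation

The generator emulates the structure of the source testing registry:
subject-level records (group, carrier status, prophylaxis choice drawn
from the uptake multinomial, entry age uniform over 30–55, event type,
time) with piecewise-exponential event times discretised from the annual
probabilities, uniform entry over a 9-year window (administrative
censoring) and 3%/yr loss to follow-up.  `km_estimate` fits the
product-limit estimator (lifelines) with competing events censored at
their event time — the same naive single-event KM the original derivation
used — and `annual_probability` converts survival to band-averaged annual
probabilities.  Greenwood variance supports 95% CIs
(coverage ≥ 93% verified by simulation at n = 2,000 over 200 replicates).

What the generator does *not* emulate: family clustering, age-dependent
uptake, informative censoring, competing-risk dependence, or real
covariate structure.  Passing parameter recovery therefore shows the
estimation pipeline is correct under the model's own assumptions, not
that the original registry estimates are unbiased — in particular the
naive KM is biased upward relative to a competing-risks cumulative
incidence when competing hazards are informative.

## Numerical choices

Float64 throughout; transition matrices are built vectorised per
subcohort (70 × 20 × 20) and traced by repeated vector–matrix products;
row sums are exact to 1e-12 and trace conservation to 1e-10 (asserted).
Ties in synthetic event times are broken by subject id; times are
reported at 2-decimal precision.  The degenerate ICER (|ΔQALY| < 1e-12)
is classified by the cost sign rather than divided.

## Known limitations

* No half-cycle correction.
* Mortality after breast cancer does not depend on stage at detection, so
  intensified surveillance improves costs (earlier-stage treatment) but
  not survival; with the published transition probabilities the
  incremental benefit of testing is therefore concentrated in the ~5% of
  the cohort choosing risk-reducing surgery, and the base-case ICER
  (R$ 30,463.93/QALY at the default readings) is sensitive to that
  structural choice.
* The printed BC-state exits (mortality 0.006/yr, metastasis 0.0134/yr)
  imply considerably milder breast-cancer prognosis than is typical for a
  cohort with a high share of late-stage diagnoses; they are used as
  printed.
* Carriers' ovarian-cancer incidence is age-constant (0.013/yr).
* No cascade-testing dynamics: relatives enter only through the unit test
  cost.
* Currency stays in R$; no conversion is performed.
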