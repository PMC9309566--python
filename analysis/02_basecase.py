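#!/usr/bin/env python
"""Base-case cost-effectiveness of BRCA1/2 testing versus no testing.

Evaluates both decision-tree arms over the 70-year Markov cohort model at a
5% discount rate and reports per-strategy discounted costs, QALYs and life
years, the incremental results, and the ICER per QALY and per life year.

Writes results/basecase.json.
"""

import json
from pathlib import Path

from hboc_cea import evaluate_icer, load_parameters, validate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = load_parameters()
    findings = validate(params)
    assert not findings, findings
    res = evaluate_icer(params)

    (RESULTS / "basecase.json").write_text(json.dumps(res.to_dict(), indent=2) + "\n")

    print("strategy            cost (R$)     QALYs   life years")
    for s in (res.comparator, res.reference):
        print(f"{s.arm:<18s} {s.cost:>10.2f} {s.qaly:>9.3f} {s.ly:>11.3f}")
    print(f"incremental        {res.d_cost:>10.2f} {res.d_qaly:>9.4f} "
          f"{res.d_ly:>11.4f}")
    print(f"ICER: R$ {res.icer_qaly:,.2f} per QALY; "
          f"R$ {res.icer_ly:,.2f} per life year ({res.dominance})")
    print(f"-> {RESULTS / 'basecase.json'}")


if __name__ == "__main__":
    main()
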