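#!/usr/bin/env python
"""One-way deterministic sensitivity analysis (tornado).

Re-runs both strategies with each uncertain input at its low and high bound
and records the resulting ICER per QALY, ordered by bar width.  An empty
ICER cell means the comparison stopped being a trade-off at that bound
(the testing strategy was dominated there).

Writes results/tornado.csv.
"""

from pathlib import Path

import pandas as pd

from hboc_cea import load_parameters, run_dsa
from hboc_cea.cea import load_dsa_scenarios

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = load_parameters()
    scenarios = run_dsa(params, load_dsa_scenarios())
    df = pd.DataFrame([{
        "parameter": s.name, "path": s.path, "low": s.low, "high": s.high,
        "icer_low": None if s.icer_low is None else round(s.icer_low, 2),
        "icer_high": None if s.icer_high is None else round(s.icer_high, 2),
    } for s in scenarios])
    df.to_csv(RESULTS / "tornado.csv", index=False)
    print(df.to_string(index=False))
    print(f"-> {RESULTS / 'tornado.csv'}")


if __name__ == "__main__":
    main()
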