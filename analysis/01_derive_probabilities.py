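#!/usr/bin/env python
"""Derive annual transition probabilities from a synthetic testing registry.

The model's transition probabilities come from time-to-event records of
women tested for BRCA1/2 variants (2,307 women, 2011-2020).  That registry
is not public, so this step generates a synthetic extract with the same
structure, runs the Kaplan-Meier derivation stratum by stratum, and checks
that every input probability is recovered within its 95% CI.

Writes results/registry_synthetic.csv and results/recovery.csv.
"""

import argparse
from pathlib import Path

from hboc_cea import (SyntheticCohortSpec, load_parameters, records_to_csv,
                      recovery_report, simulate_cohort)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-stratum", type=int, default=5000)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    params = load_parameters()
    spec = SyntheticCohortSpec(rates=params.probabilities, seed=args.seed)
    records = simulate_cohort(spec)
    records_to_csv(records, str(RESULTS / "registry_synthetic.csv"))
    print(f"synthetic registry: {len(records)} women "
          f"({sum(r.carrier for r in records)} carriers) "
          f"-> {RESULTS / 'registry_synthetic.csv'}")

    report = recovery_report(params.probabilities,
                             n_per_stratum=args.n_per_stratum, seed=args.seed)
    report.to_csv(RESULTS / "recovery.csv", index=False)
    covered = int(report["covered"].sum())
    print(f"parameter recovery at n={args.n_per_stratum}/stratum: "
          f"{covered}/{len(report)} within the 95% CI "
          f"-> {RESULTS / 'recovery.csv'}")
    worst = report.assign(err=(report.estimate - report.truth).abs()) \
                  .nlargest(3, "err")[["parameter", "truth", "estimate"]]
    print("largest absolute deviations:")
    print(worst.to_string(index=False))


if __name__ == "__main__":
    main()
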