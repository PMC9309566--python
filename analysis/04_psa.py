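#!/usr/bin/env python
"""Probabilistic sensitivity analysis (10,000 Monte Carlo draws).

Samples every uncertain parameter from its fitted beta (probabilities,
utilities) or gamma (costs, 40% CV) distribution, re-runs both strategies
per draw, and summarises the incremental cloud as a cost-effectiveness
acceptability curve and an incremental net-monetary-benefit curve over a
willingness-to-pay grid of R$ 0-150,000 per QALY.

Writes results/ce_plane.csv and results/ceac.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hboc_cea import ceac_threshold, load_parameters, run_psa

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=10_000)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    params = load_parameters()
    psa = run_psa(params, args.n, seed=args.seed)

    pd.DataFrame({"sample_id": np.arange(psa.n_samples), "d_cost": psa.d_cost,
                  "d_qaly": psa.d_qaly}).to_csv(RESULTS / "ce_plane.csv",
                                                index=False, float_format="%.6f")
    pd.DataFrame({"wtp": psa.wtp_grid, "p_cost_effective": psa.ceac,
                  "inmb": psa.inmb}).to_csv(RESULTS / "ceac.csv", index=False,
                                            float_format="%.6f")

    idx = int(np.argmax(psa.wtp_grid == 25_000.0))
    thr = ceac_threshold(psa, 0.5)
    ne = float(np.mean((psa.d_cost > 0) & (psa.d_qaly > 0)))
    print(f"{psa.n_samples} draws over {len(psa.sampled_paths)} uncertain parameters")
    print(f"CE plane: {100 * ne:.1f}% of draws in the dearer-but-better quadrant")
    print(f"P(cost-effective at R$ 25,000/QALY) = {100 * psa.ceac[idx]:.2f}%")
    print(f"CEAC reaches 50% at WTP = "
          f"{'R$ %.0f' % thr if thr is not None else 'above grid max'}")
    print(f"-> {RESULTS / 'ce_plane.csv'}, {RESULTS / 'ceac.csv'}")


if __name__ == "__main__":
    main()
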