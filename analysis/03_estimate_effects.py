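#!/usr/bin/env python
"""Estimate counterfactual survival under all four treatment strategies.

Fits the multinomial treatment model and the interaction logistic outcome
model, reports IP-weighted, standardized and doubly robust counterfactual
means, the derived causal contrasts (risk differences, relative increases,
risk ratios, drug-drug interaction), and the covariate balance achieved by
IP weighting.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import drcausal as dc

ARMS = ("no_drug", "memantine", "donepezil", "combined")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort_filtered.csv"))
    ap.add_argument("--spec", type=Path, default=Path("results/cohort_spec.yaml"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    warnings.simplefilter("ignore", RuntimeWarning)

    spec = dc.spec_from_yaml(args.spec)
    cohort = dc.read_cohort_csv(args.cohort)
    matrix = dc.build_analysis_matrix(cohort, spec.schema)

    cf, eff = dc.estimate_all(matrix)
    means = pd.DataFrame(
        {"arm": ARMS, "ip_weighted": cf.means_ip, "standardized": cf.means_st,
         "doubly_robust": cf.means_dr}
    )
    means.to_csv(args.outdir / "counterfactual_means.csv", index=False)

    effects = pd.DataFrame(
        {"contrast": [f"combined_vs_{a}" for a in ARMS[:3]],
         "risk_difference": eff.rds, "relative_increase_pct": eff.rel_pct,
         "risk_ratio": eff.rrs}
    )
    effects.to_csv(args.outdir / "causal_effects.csv", index=False)

    pfit = dc.fit_multinomial(matrix)
    probs = dc.predict_probs(pfit, matrix.L)
    balance = dc.smd_balance(matrix, probs)
    balance.to_csv(args.outdir / "smd_balance.csv")

    print("counterfactual five-year survival:\n", means.round(3).to_string(index=False))
    print("\ncausal effects (doubly robust):\n", effects.round(3).to_string(index=False))
    print(f"\nadditive drug-drug interaction: {eff.ddi:.3f}")
    print(f"weighted balance: max |SMD| = {np.abs(balance.to_numpy()).max():.3f} "
          f"over {balance.size} covariate-pair cells")


if __name__ == "__main__":
    main()
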