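"""Between-individual rate variation: how much does it inflate the
predicted gainer percentage?

Sweeps the between-individual rate SD for a Steenstrup-like design
(30.8 bp/yr over 10.9 years, sigma_d 158.9 bp) and demonstrates
method-of-moments recovery of the rate SD from simulated cohorts. Writes
results/random_effects_sweep.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from telogain import (
    CohortParams,
    MixedModelParams,
    estimate_sigma_between,
    measured_changes,
    mixed_gainer_probability,
    simulate_cohort,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "random_effects_sweep.csv"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    mu, t, sigma_d = 30.8, 10.9, 158.9
    rows = [{
        "sigma_between": sb,
        "gainer_pct": 100 * mixed_gainer_probability(MixedModelParams(
            mu_rate=mu, sigma_between=sb, followup_years=t, sigma_d=sigma_d)),
    } for sb in np.arange(0.0, 41.0, 2.5)]
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    frame.to_csv(OUT, index=False)
    print(f"wrote {OUT}")
    print(frame.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    fixed = frame.gainer_pct.iloc[0]
    print(f"\nfixed-rate prediction: {fixed:.1f}%. A rate SD of 15-20 bp/yr "
          f"raises it to {frame.set_index('sigma_between').gainer_pct[15.0]:.1f}-"
          f"{frame.set_index('sigma_between').gainer_pct[20.0]:.1f}% — "
          "rate heterogeneity always pushes the prediction toward the observed values.")

    truth = 15.0
    estimates = []
    for i in range(50):
        params = CohortParams(
            n_individuals=2000, baseline_mean=5840.0, baseline_sd=600.0,
            attrition_mean_rate=mu, attrition_sd_rate=truth, error_sd=sigma_d,
            followup_years=t, replicates_baseline=2, replicates_followup=2,
            seed=args.seed * 1000 + i)
        changes = measured_changes(simulate_cohort(params))
        estimates.append(estimate_sigma_between(changes, sigma_d, t))
    print(f"\nmoment recovery of a true rate SD of {truth} bp/yr over 50 "
          f"cohorts of n=2000: mean {np.mean(estimates):.2f}, "
          f"SD {np.std(estimates):.2f} bp/yr.")


if __name__ == "__main__":
    main()
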