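"""Study-design calculator: how long must the follow-up be?

Inverts the misclassification curve to tabulate the follow-up duration
needed to keep the expected fraction of artifactual TL gainers below a
target, across assay CVs and replicate schemes (30 bp/yr attrition, 7 kb
mean LTL). Writes results/required_followup.csv.
"""

from pathlib import Path

import pandas as pd

from telogain import required_followup

OUT = Path(__file__).resolve().parents[1] / "results" / "required_followup.csv"


def main() -> None:
    rows = [
        {
            "cv_pct": 100 * cv,
            "replicates": r,
            "target_pct": target,
            "required_years": required_followup(cv, r, 30.0, target),
        }
        for cv in (0.01, 0.02, 0.03, 0.05)
        for r in (1, 2)
        for target in (1.0, 5.0, 10.0)
    ]
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    frame.to_csv(OUT, index=False)
    print(f"wrote {OUT}")
    print(frame.pivot_table(index=["cv_pct", "replicates"], columns="target_pct",
                            values="required_years").round(1).to_string())
    print("\nreading: a duplicate-measured 2% CV assay needs ~7.7 years to "
          "keep artifactual gainers under 5%; a single-measured 5% CV assay "
          "needs ~27 years — longitudinal designs must budget follow-up "
          "against their assay's CV, not against convenience.")


if __name__ == "__main__":
    main()
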