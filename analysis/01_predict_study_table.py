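"""Per-study predictions: how many apparent TL gainers does measurement
error alone explain in each published longitudinal cohort?

Writes results/study_predictions.csv with the full computation trace
(mu_total, sigma, sigma_d, z, predicted %) for every catalog row, keeping
the rows that cannot be predicted with their exclusion reason.
"""

from pathlib import Path

from telogain import builtin_table1
from telogain.report import predict_table_frame

OUT = Path(__file__).resolve().parents[1] / "results" / "study_predictions.csv"


def main() -> None:
    catalog = builtin_table1()
    frame = predict_table_frame(catalog)
    OUT.parent.mkdir(exist_ok=True)
    frame.to_csv(OUT, index=False)

    computable = frame.dropna(subset=["predicted_pct"])
    print(f"wrote {OUT} ({len(frame)} studies, {len(computable)} predictable)")
    print(computable[["study_id", "followup_years", "method", "cv_pct",
                      "observed_gainers_pct", "predicted_pct"]]
          .to_string(index=False))
    gap = computable.observed_gainers_pct - computable.predicted_pct
    print(f"\nobserved minus predicted gainers: median {gap.median():.1f} "
          f"points (predicted <= observed in {int((gap >= 0).sum())} of "
          f"{len(computable)} studies) — measurement error alone accounts "
          "for most, but not all, of the reported 'lengthening'.")


if __name__ == "__main__":
    main()
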