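"""Report tables: per-study predictions and theoretical curves.

Shared by the command-line interface and the analysis drivers so that both
produce byte-identical CSVs from the same inputs.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .catalog import StudyRecord
from .error_model import curve_table, predict_study, round_half_away

__all__ = ["predict_table_frame", "curve_panels", "DEFAULT_CV_GRID"]

#: CV grid (fractions) used for the default theoretical-curve panels.
DEFAULT_CV_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06)


def predict_table_frame(
    records: Sequence[StudyRecord],
    cv_overrides: Optional[Mapping[str, float]] = None,
    mean_tl: Union[str, float] = "midpoint",
    decimals: int = 1,
) -> pd.DataFrame:
    """One row per study with observed and predicted gainer percentages.

    Rows whose inputs are insufficient keep a blank prediction and carry
    the reason in the ``excluded`` column, mirroring the blank cells of the
    published table. ``cv_overrides`` maps study_id to a replacement CV
    (fraction), e.g. to re-evaluate a study with an impartially measured CV.
    """
    columns = [
        "study_id", "year", "n", "followup_years", "method", "units",
        "cv_pct", "replicates", "observed_gainers_pct", "mu_total", "sigma",
        "sigma_d", "z", "predicted_pct", "excluded",
    ]
    cv_overrides = dict(cv_overrides or {})
    rows = []
    for rec in records:
        row: dict = {
            "study_id": rec.study_id,
            "year": rec.year,
            "n": rec.n,
            "followup_years": rec.followup_years,
            "method": rec.method,
            "units": rec.units,
            "cv_pct": None if rec.cv is None else 100.0 * rec.cv,
            "replicates": rec.replicates,
            "observed_gainers_pct": rec.observed_gainers_pct,
            "mu_total": None,
            "sigma": None,
            "sigma_d": None,
            "z": None,
            "predicted_pct": None,
            "excluded": "",
        }
        override = cv_overrides.get(rec.study_id)
        reason = rec.incomplete_for_prediction
        can_override_cv = reason == "cannot predict: missing cv" and override is not None
        if reason is None or can_override_cv:
            pred = predict_study(rec, cv_override=override, mean_tl=mean_tl)
            row.update(
                mu_total=pred.mu_total,
                sigma=pred.sigma,
                sigma_d=pred.sigma_d,
                z=pred.z,
                predicted_pct=round_half_away(100.0 * pred.probability, decimals),
            )
            if override is not None:
                row["cv_pct"] = 100.0 * override
        else:
            row["excluded"] = reason
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def curve_panels(
    cv_list: Sequence[float] = DEFAULT_CV_GRID,
    rates: Sequence[float] = (30.0, 20.0),
    replicate_schemes: Sequence[int] = (2, 1),
    fu_grid: Optional[Sequence[float]] = None,
    mean_tl: float = 7000.0,
) -> pd.DataFrame:
    """Four-panel theoretical curve table (replicates x attrition rate).

    The default grids span single and duplicate measurements crossed with
    attrition rates of 30 and 20 bp/yr at an assumed 7 kb mean LTL — the
    panel layout of the theoretical-curve figure. Long format: one row per
    (cv, replicates, rate, follow-up) cell.
    """
    kwargs = {} if fu_grid is None else {"fu_grid": fu_grid}
    panels = [
        curve_table(cv_list, attrition_rate=rate, replicates=r, mean_tl=mean_tl, **kwargs)
        for r in replicate_schemes
        for rate in rates
    ]
    return pd.concat(panels, ignore_index=True)
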