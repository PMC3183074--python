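"""Readers for the deposited per-animal data tables, and the replication of
the published regression battery on them.

Two tables are supported, by a user-editable column mapping (the deposited
files do not document a fixed schema):

* a raw long-format timecourse table (one row per animal / age / biomarker);
* a per-animal summary table (lifespan plus day-window mean/slope columns).

:func:`replicate` runs the standard battery of lifespan regressions —
univariate and bivariate day-3-7 summary models per biomarker plus the
seven-predictor survival index — on a summary table, reporting in-sample and
leave-one-out R-squared for each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import stats as wstats

__all__ = ["ColumnSchema", "read_timecourse_table", "read_summary_table",
           "replicate", "REGRESSION_BATTERY"]


@dataclass
class ColumnSchema:
    """Mapping from the canonical column names to those found in a file."""

    animal_id: str = "animal_id"
    dataset_id: str = "dataset_id"
    lifespan_days: str = "lifespan_days"
    age_days: str = "age_days"
    biomarker: str = "biomarker"
    value: str = "value"

    @classmethod
    def from_yaml(cls, path) -> "ColumnSchema":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def read_timecourse_table(path, schema: Optional[ColumnSchema] = None,
                          ) -> pd.DataFrame:
    """Long-format raw timecourses: animal_id, age_days, biomarker, value."""
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, comment="#")
    cols = {schema.animal_id: "animal_id", schema.age_days: "age_days",
            schema.biomarker: "biomarker", schema.value: "value"}
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"timecourse table lacks columns {missing}; "
                         "adjust the column schema")
    return df.rename(columns=cols)[list(cols.values())]


def read_summary_table(path, schema: Optional[ColumnSchema] = None,
                       ) -> pd.DataFrame:
    """Per-animal summary table indexed by animal id.

    Expects a lifespan column plus ``<biomarker>_mean`` / ``<biomarker>_slope``
    day-window summaries (any set of biomarkers).
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, comment="#")
    if schema.animal_id not in df.columns:
        raise ValueError(f"summary table lacks {schema.animal_id!r}")
    if schema.lifespan_days not in df.columns:
        raise ValueError(f"summary table lacks {schema.lifespan_days!r}")
    df = df.rename(columns={schema.animal_id: "animal_id",
                            schema.lifespan_days: "lifespan_days"})
    return df.set_index("animal_id")


#: The printed regression battery: model name -> summary-column predictors.
REGRESSION_BATTERY: Dict[str, Tuple[str, ...]] = {
    "length": ("length_slope", "length_mean"),
    "autofluorescence": ("autofluorescence_mean", "autofluorescence_slope"),
    "motion": ("motion_mean", "motion_slope"),
    "texture": ("texture_mean", "texture_slope"),
    "mir71": ("mir71_mean", "mir71_slope"),
    "mir71_pc": ("pc1_score_mean", "pc1_score_slope"),
    "mir246": ("mir246_slope",),
    "mir239": ("mir239_slope",),
    "survival_index": wstats.SURVIVAL_INDEX_PREDICTORS,
}


def replicate(summaries: pd.DataFrame,
              battery: Optional[Dict[str, Tuple[str, ...]]] = None,
              ) -> Dict[str, wstats.RegressionResult]:
    """Run the regression battery on a summary table.

    Models whose predictor columns are absent from the table are skipped
    (the deposited datasets measured different marker panels); each fitted
    model carries in-sample R-squared, F/p and the leave-one-out R-squared.
    """
    battery = battery or REGRESSION_BATTERY
    out: Dict[str, wstats.RegressionResult] = {}
    y_all = summaries["lifespan_days"]
    for name, predictors in battery.items():
        cols = [c for c in predictors]
        if any(c not in summaries.columns for c in cols):
            continue
        sub = summaries[cols + ["lifespan_days"]].dropna()
        if sub.shape[0] <= len(cols) + 1:
            continue
        res = wstats.ols_predict(sub[cols], sub["lifespan_days"])
        res.loo_r2 = wstats.loo_r2(sub[cols], sub["lifespan_days"])
        out[name] = res
    return out
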