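"""Univariate and multivariate lifespan regression on the day-3-7 summaries
of the simulated cohort: the regression battery, leave-one-out validation,
the seven-predictor survival prediction index, and the dichotomized
diagnostic test.

Reads results/analysis/summaries.csv (from 01_simulate_cohort.py).
"""

import pandas as pd

from wormspan import stats as ws
from wormspan import supplementary as supp

summaries = supp.read_summary_table("results/analysis/summaries.csv")
results = supp.replicate(summaries)

print(f"{'model':18s} {'R2':>6s} {'loo R2':>7s} {'p':>10s}")
for name, res in results.items():
    print(f"{name:18s} {res.r2:6.3f} {res.loo_r2:7.3f} {res.p_value:10.2e}")

idx = results["survival_index"]
print("\nsurvival-index standardized weights (descending magnitude):")
for name, w in idx.weights_by_magnitude():
    print(f"  {name:24s} {w:+.3f}")

cols = list(ws.SURVIVAL_INDEX_PREDICTORS)
sub = summaries[cols + ["lifespan_days"]].dropna()
pred = ws.ols_predict(sub[cols], sub["lifespan_days"]).predictions
test = ws.dichotomize_test(pred, sub["lifespan_days"])
print(f"\nabove/below-average survival index as a diagnostic test: "
      f"sensitivity {test.sensitivity:.2f}, specificity {test.specificity:.2f}, "
      f"mean-lifespan ratio {test.mean_lifespan_ratio:.2f} "
      f"(KS p = {test.ks_p:.2e})")

rows = [{"model": k, "r2": v.r2, "loo_r2": v.loo_r2, "p": v.p_value}
        for k, v in results.items()]
pd.DataFrame(rows).to_csv("results/analysis/regression_battery.csv",
                          index=False)
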