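"""Quantify model skill and the improvement attributable to the model update.

Computes overall and per-period skill metrics, the stratified
random-sampling ensemble scores by month and by node, the percentage
improvement over the months observed in both years, and the supporting
correlation/regression analyses of raw group summaries.
"""

import pandas as pd

from benthoval import skillstats as sk
from _common import RESULTS, result

res = result()
vt = res.validation

print("overall skill:", {k: round(v, 3) for k, v in res.overall.as_dict().items()
                         if k in ("n", "mb", "me", "rmse", "r", "d")})
for name, scores in res.by_period.items():
    print(f"  {name}: n={scores.n}, MB={scores.mb:.3f}, ME={scores.me:.3f}, "
          f"RMSE={scores.rmse:.3f}, R={scores.r:.3f}, d={scores.d:.3f}")

print("ensemble-average scores (month strata):",
      {k: round(v, 3) for k, v in res.ensemble_month.ensemble.items()
       if k in ("mb", "me", "rmse", "r", "d")})

imp = res.improvement
print("mean percentage improvement (Mar-May, year over year):",
      {k: round(v, 2) for k, v in imp.mean_p.items()})
print(f"  error metrics use {imp.error_formula}; bounded use {imp.bounded_formula}")

corr = sk.correlate_group_summaries(vt, "node")
reg = sk.regress_scores_on_depth(res.ensemble_node.per_stratum,
                                 dict(zip(res.mesh.node_ids, res.mesh.h)))

pd.DataFrame([res.overall.as_dict()]).to_csv(RESULTS / "skill_overall.csv", index=False)
res.ensemble_month.per_stratum.to_csv(RESULTS / "ensemble_month.csv", index=False)
res.ensemble_node.per_stratum.to_csv(RESULTS / "ensemble_node.csv", index=False)
imp.per_month.to_csv(RESULTS / "improvement_per_month.csv", index=False)
corr.to_csv(RESULTS / "correlations.csv", index=False)
reg.to_csv(RESULTS / "depth_regression.csv", index=False)
print(f"wrote skill, ensemble, improvement, correlation and regression tables to {RESULTS}")
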