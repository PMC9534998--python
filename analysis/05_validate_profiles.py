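"""Validate modelled temperature-depth profiles against capture ascents.

Extracts each angling event from the archival record (last seabed record to
first surface record), pairs the observed ascent with the modelled sigma-layer
profile at the nearest node and hour, and writes per-event tables and figures.
No headline skill metrics are computed for profiles: observation depths and
layer depths do not coincide and the sample is small.
"""

import pandas as pd

from benthoval import plots
from _common import RESULTS, result

res = result()

print(f"{len(res.events)} angling events "
      f"({(res.events['event_type'] == 'liberty').sum()} at liberty, "
      f"{(res.events['event_type'] == 'retrieval').sum()} retrieval)")

rows = []
for i, pair in enumerate(res.profiles, start=1):
    ev = pair.event
    diag = pair.diagnostics["diff_c"]
    rows.append({"profile": i, "start": ev.start,
                 "duration_min": ev.duration.total_seconds() / 60,
                 "n_obs": len(pair.observed),
                 "median_layer_diff_c": diag.median()})
    mod = pair.modelled.assign(role="modelled")
    obs = pair.observed.assign(role="observed")
    pd.concat([mod, obs], ignore_index=True).to_csv(
        RESULTS / f"profile_{i:02d}.csv", index=False)
    plots.profile_figure(pair, RESULTS / f"profile_{i:02d}.png")

summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "profiles_summary.csv", index=False)
print(summary.to_string(index=False))
print(f"total profile observations: {summary['n_obs'].sum()}")
print(f"wrote per-event profile CSVs and figures to {RESULTS}")
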