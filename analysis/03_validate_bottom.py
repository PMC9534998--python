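"""Assemble the node-hour bottom-temperature validation dataset.

Links archival records to simultaneous valid detections (same individual,
within 30 min and the same calendar hour), averages observed temperatures per
node-hour, pairs them with modelled seabed-layer temperatures and summarises
validation effort through time and space.
"""

from benthoval import plots
from _common import RESULTS, result

res = result()
vt, eff = res.validation, res.effort

print(f"validation dataset: {len(vt):,} node-hour observations at "
      f"{eff['n_nodes']} nodes over {eff['span_days']} days "
      f"({eff['gap_days']} days without observations)")
top = eff["obs_per_node"].sort_values("pct", ascending=False).iloc[0]
print(f"effort is concentrated: node {int(top['node_id'])} alone holds "
      f"{top['pct']:.0f}% of observations")
print("observations by depth class:",
      dict(eff["obs_per_depth_class"]))

vt.to_csv(RESULTS / "validation.csv", index=False)
eff["obs_per_node"].to_csv(RESULTS / "effort_per_node.csv", index=False)
eff["obs_per_day"].rename_axis("day").to_csv(RESULTS / "effort_per_day.csv")
plots.effort_figure(vt, RESULTS / "effort.png")
print(f"wrote validation.csv, effort tables and effort.png to {RESULTS}")
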