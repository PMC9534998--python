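"""Simulate the study system: mesh, biased model fields, tagged animals.

Generates the synthetic mesh and hourly temperature/elevation fields with the
two-period bias schedule (+0.53 degC through 2016, -0.045 degC after the
new-year model update), tracks the tagged animals, samples their archival
tags and simulates acoustic detections and angling events.  Writes the raw
tag-side data products (the model fields stay in memory; they are regenerated
deterministically from the seed by every downstream script).
"""

from _common import CONFIG, RESULTS, result

res = result()

res.archival.to_csv(RESULTS / "archival.csv", index=False)
res.detections.drop(columns=["is_false"]).to_csv(RESULTS / "detections.csv", index=False)
res.receivers.to_csv(RESULTS / "receivers.csv", index=False)
res.events.to_csv(RESULTS / "events.csv", index=False)

print(f"seed {CONFIG.seed}: {res.mesh.n_nodes} nodes, "
      f"{len(res.truth_and_model.truth.hours)} field hours")
print(f"{res.archival['individual_id'].nunique()} individuals, "
      f"{len(res.archival):,} archival records, "
      f"{len(res.detections):,} detections at {len(res.receivers)} receivers, "
      f"{len(res.events)} angling events")
print(f"wrote archival/detections/receivers/events CSVs to {RESULTS}")
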