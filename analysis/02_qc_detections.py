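"""Quality-control acoustic detections and localise them onto mesh nodes.

Applies the short-interval criterion (a detection needs a companion detection
of the same transmitter at the same receiver within 30 min) and maps each
surviving detection to the mesh node nearest its receiver.
"""

from _common import RESULTS, result

res = result()

kept, removed = len(res.detections_valid), len(res.detections) - len(res.detections_valid)
print(f"short-interval filter: kept {kept:,} / {len(res.detections):,} "
      f"({100 * kept / len(res.detections):.1f}%), removed {removed:,}")

injected = res.detections["is_false"]
false_removed = injected.sum() - res.detections_valid["is_false"].sum()
print(f"of {injected.sum():,} injected false detections, "
      f"{false_removed:,} ({100 * false_removed / injected.sum():.1f}%) were removed")

res.qc_report.to_csv(RESULTS / "qc_report.csv", index=False)
res.detections_valid.drop(columns=["is_false"]).to_csv(
    RESULTS / "detections_valid.csv", index=False
)
print(f"wrote qc_report.csv and detections_valid.csv to {RESULTS}")
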