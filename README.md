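# benthoval

Validation of hydrodynamic-model temperatures with benthic animal-borne
sensors, passive acoustic telemetry and angler mark-recapture records.

## The problem

Regional ocean models such as FVCOM-based coastal systems resolve temperature
on an unstructured triangular mesh with terrain-following sigma layers, but
near-seabed validation data are scarce: ships and gliders rarely sample the
bottom boundary layer. Benthic animals do. A skate carrying an archival tag
records depth and temperature every two minutes while sitting on the seabed;
moored acoustic receivers detecting its transmitter localise it to within the
detection range (~425 m, i.e. ~0.57 km² — comparable to the mesh resolution).
When the animal is hooked by an angler and pulled to the surface, its tag
samples an opportunistic temperature–depth profile of the whole water column.

This package implements that validation pipeline end to end, together with a
synthetic-data generator that emulates every input (mesh, hourly fields with a
*known* model-minus-truth bias schedule, benthic movement, tag quantisation
and noise, logistic detection, capture ascents), so the full analysis is
testable without any external data download.

## The method

For node-hour pairs of modelled (M) and observed (O) bottom temperature, skill
is summarised by

- Mean Bias `MB = mean(M − O)`,
- Mean Error `ME = mean|M − O|`,
- `RMSE = sqrt(mean((M − O)²))`,
- Pearson's `R`,
- Willmott's Index of Agreement `d = 1 − Σ(M−O)² / Σ(|M−Ō| + |O−Ō|)²`,

plus normalised variants (divided by Ō). Because raw metrics confound skill
with sample size and mean temperature, ensemble-average scores use a
five-stage stratified random-sampling algorithm: keep (node, month) cells with
at least `max(5, 25th percentile)` observations; draw 5 without replacement
per cell; compute all metrics; repeat 1,000 times; summarise each cell by the
median across draws; average cells across nodes (per month) or months (per
node). Improvement between model versions is the per-month percentage change
in these ensemble scores, `P = 100·(|s_base| − s_upd·sign(s_base))/|s_base|`
for error metrics (overshooting zero scores above 100%), averaged over the
months observed in both periods.

Detections are quality-controlled with a short-interval criterion (a
detection needs a companion of the same transmitter at the same receiver
within 30 min), archival records are linked to the temporally nearest valid
detection within 30 min in the same calendar hour, and layer depths during
capture ascents are `|σ̃_k|·(h + ζ)` with ζ the tidal elevation at the hour
nearest the event start.

## Worked example

The numbered scripts under `analysis/` run the full synthetic study (seed 1:
three tagged individuals tracked March 2016 – June 2017 over a model with a
+0.53 °C warm bias through 2016 and a −0.045 °C residual bias after a
new-year model update), writing tables and figures to `results/analysis/`:

```sh
cd analysis
python 01_simulate.py
python 02_qc_detections.py
python 03_validate_bottom.py
python 04_skill_and_improvement.py
python 05_validate_profiles.py
python 06_diagnostics.py
```

`04_skill_and_improvement.py` prints:

```
overall skill: {'n': 10120, 'mb': 0.356, 'me': 0.384, 'rmse': 0.445, 'r': 0.998, 'd': 0.996}
  baseline: n=7049, MB=0.531, ME=0.531, RMSE=0.531, R=1.000, d=0.992
  updated: n=3071, MB=-0.046, ME=0.048, RMSE=0.055, R=1.000, d=1.000
mean percentage improvement (Mar-May, year over year): {'mb': 108.73, 'me': 90.84, 'rmse': 89.77, 'r': -1075.22, 'd': 83.23}
```

Reading this: 10,120 node-hour observations were assembled; over the biased
period the pipeline recovers the injected +0.53 °C bias to three decimals
(MB = 0.531); after the simulated model update the residual −0.045 °C bias is
likewise recovered, and the ensemble-average Mean Bias improves by ≈109% —
above 100% because the update overshoots zero. The negative `P` for `R`
reflects that the baseline correlation was already ≈1, leaving no headroom.
`02` shows the short-interval filter removing 99.5% of injected false
detections, and `06` shows neighbour-node and hour-to-hour variability of the
modelled seabed field (≈0.008 / 0.022 °C) sitting well below the 0.1 °C tag
accuracy, which is what justifies nearest node-and-hour pairing.

The same machinery is importable as a library:

```python
from benthoval import RunConfig, run_pipeline
res = run_pipeline(RunConfig(seed=1))
print(res.by_period["baseline"].mb)       # 0.5306
print(res.improvement.mean_p["mb"])       # 108.73
```

## Layout

- `src/benthoval/` — the library: `meshfield` (mesh, sigma layers, fields,
  NetCDF I/O), `synthdata` (the generator), `telemetry` (detection QC),
  `bottomval` (validation dataset and effort), `skillstats` (metrics,
  stratified ensemble, improvement), `profileval` (capture ascents),
  `diagnostics`, `pipeline` (orchestration), `plots`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and end-to-end acceptance tests.
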