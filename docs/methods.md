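# Methods

This note documents the models, algorithms and design choices behind
`benthoval`: what is simulated, how the validation statistics are defined,
which parameters matter, and what the synthetic experiments do and do not
demonstrate about real data.

## Model grid and fields

Scalar fields live on an unstructured triangular mesh (FVCOM convention:
scalars at nodes, one value per sigma layer per hour). Sigma levels run from
0 at the surface to −1 at the seabed; with L layers the centre of layer k is
σ̃_k = (σ_{k−1} + σ_k)/2 and its depth below the instantaneous surface is
|σ̃_k|·(h + ζ), where h is bathymetry (m below mean sea level, positive) and
ζ tidal elevation (m, positive up). We use 11 uniformly spaced sigma *levels*
bounding 10 *layers* by default, with the seabed layer at index 10;
non-uniform level vectors are accepted. Coordinates are planar metres
(projected grid); all distance arithmetic is Euclidean.

Nearest-node lookup is an exhaustive distance scan with ties broken by lowest
node id — meshes here are small (hundreds of nodes) and determinism matters
more than asymptotics. Time lookup snaps to the nearest hourly stamp within
±30 min; outside that the operation errors rather than extrapolate. Fields
round-trip through classic NetCDF (xarray, scipy backend) with 1-based
connectivity.

## Synthetic study system

The generator emulates a fjordic shelf site and a ~15-month tag deployment.
Scientific intent: every downstream stage must be testable against known
ground truth, so the model field is constructed as truth plus an exactly
known bias schedule, and tags observe truth through their published error
model.

- **Mesh and bathymetry.** Delaunay triangulation of a rectangle (boundary
  frame included, so the hull is the rectangle); bathymetry is a sloping base
  plus Gaussian basins/platforms min–max rescaled to 5–290 m (no clipping
  plateaus).
- **Temperature truth.** Sinusoidal seasonal cycle spanning ≈6–16 °C peaking
  in mid-August; summer-only thermal stratification with a Gaussian seasonal
  envelope (default peak magnitude 1.5 °C, giving a July surface-to-seabed
  contrast in the 1–2 °C band), linear in σ so the seabed layer is
  unaffected; a small smooth spatial gradient (0.2 °C across the domain); and
  a site-wide AR(1) hourly anomaly (sd 0.05 °C, φ = 0.8) so neighbour-node
  and hour-to-hour variability diagnostics come out small, as observed at the
  real site. Tidal elevation is an M2-like sinusoid (amplitude 0.8 m, chosen
  so the seabed-layer depth modulation is a few tenths of a metre per hour,
  the scale the study site exhibits).
- **Bias schedule.** Piecewise-constant in time and (optionally) depth class.
  The default emulates a model update: +0.53 °C before 2017-01-01 and
  −0.045 °C after — the pre-update warm bias and post-update residual cool
  bias of the system this package emulates. With these values the expected
  Mean-Bias improvement is ≈108.5%.
- **Movement.** A mean-reverting (home-ranging) random walk at the tag's
  2-min sampling interval, reflected at the hull; the animal's depth is local
  bathymetry minus a small non-negative offset (benthic assumption). Step sd
  30 m per step with reversion 10⁻³ gives a stationary home range of a few
  hundred metres, keeping animals within detection range of a receiver
  cluster most of the time — matching the strong spatial concentration of
  validation effort seen with resident benthic species.
- **Archival tags.** temp = quantise(truth + N(0, 0.1 °C), 0.032 °C);
  depth = quantise(depth + N(0, 4.77 m), 0.24 m), per the tag manufacturer
  specification, every 120 s.
- **Detections.** Transmissions at a 60 s nominal delay with ±15 s uniform
  jitter (spacing never below delay − jitter); each receiver hears each
  transmission independently with logistic probability
  p(dist) = 1/(1 + exp((dist − 425)/60)) — the 425 m midpoint is the
  published detection range; the 60 m steepness is a free choice. False
  detections are injected as isolated singletons (the failure mode the
  short-interval filter targets) at 2 per receiver-day, drawn over a wide
  pool of phantom codes so they do not accidentally acquire companions.
- **Angling events.** Events anchor at times when the animal is in ≥50 m of
  water (anglers target deep water, and an ascent must be distinguishable
  from depth-sensor noise), at least an hour clear of the record ends, with
  durations drawn uniformly from 8–20 min. Ascent depths ramp linearly to the
  surface with noise at the *resolution* scale (0.12 m) and a monotone trend:
  a pressure sensor's short-term precision is near its resolution; the 4.77 m
  accuracy figure is an absolute calibration bound, and white 4.77 m noise
  would make any minutes-long ascent undetectable in principle. Ascent
  temperatures come from the truth temperature of the sigma layer containing
  the instantaneous depth.

## Validation dataset

Detections pass a short-interval criterion: keep a detection iff at least one
companion detection of the same transmitter occurs at the same receiver
within ±30 min (window, companion count and the same-receiver requirement are
configurable; the across-array variant is supported). With the default
single-companion rule the companion relation is symmetric, so the filter is
idempotent. Each valid detection is assigned the node nearest its receiver.

Archival records are linked to the temporally nearest valid detection of the
same individual when the gap is ≤30 min *and* both fall in the same UTC
calendar hour; hour bins are [h, h+1). When an individual is detected at
multiple nodes within an hour its records split by nearest detection rather
than duplicating (no double counting; duplication is available behind a
flag-equivalent by relaxing the hour rule). Archival depth is never used to
refine location — depth enters only through node bathymetry (shallow < 50 m
vs deep ≥ 50 m). One validation row per (node, hour) holds the mean observed
temperature, the modelled seabed-layer temperature, and diff = M − O.

## Skill statistics

Willmott's d is clipped to [0, 1] (it is bounded there by the triangle
inequality; floating-point residue can otherwise dip below 0). R under zero
variance and normalised metrics under Ō = 0 propagate as NaN and are excluded
from ensemble medians/means with a count.

The stratified ensemble always forms cells as (node, year-month). Selection
keeps cells with n ≥ max(5, 25th percentile of cell sizes); sampling draws 5
rows without replacement (guaranteed by selection); 1,000 seeded replicates;
per-cell median per metric; then means across nodes within month (month
strata) or across months within node (node strata), and a grand mean across
strata. Cells of exactly 5 rows degenerate to the direct metrics, as they
must. Sampling uses a single generator over cells iterated in sorted key
order, so results are bit-reproducible under the seed.

Percentage improvement per month m:
P_m = 100·(|b_m| − u_m·sign(b_m))/|b_m| for MB/ME/RMSE (an update that
overshoots zero scores above 100%), and P_m = 100·(u_m − b_m)/(1 − b_m) for
R and d (fraction of remaining headroom closed) — the bounded-metric
orientation is a genuine free choice and is recorded in the report's
metadata. Months with a zero baseline (error metrics) or unit baseline
(bounded metrics) are flagged and excluded from the mean. P for R is wildly
unstable whenever baseline R ≈ 1 (headroom ≈ 0) and should be read as a
diagnostic only.

## Profile validation

An angling event runs from the last depth observation preceding the capture
ascent to the first observation at or above a 1 m surface threshold. The
ascent is found by scanning ±2 h around the reported capture time for the
first surface record, then walking backwards while depth keeps rising by more
than one resolution step (0.24 m); a single stalled or slightly reversed
record is retained only when the record before it resumes the ascent, so flat
pre-event runs terminate the walk. Under white 4.77 m pre-event depth noise
the boundary can absorb or shed a couple of 2-min records; extracted
durations track the generated 8–20 min draws to within a few sampling steps.

The modelled profile is the full sigma-layer column at the node nearest the
event location and the hour nearest the event *start*, with layer depths
using ζ at that hour (elevation drift within an 8–20 min event moves layer
depths by centimetres — negligible against the 4.77 m depth uncertainty).
Observed points carry ±0.1 °C and ±4.77 m uncertainty. Per-layer differences
against the nearest observation by depth are computed as a diagnostic only;
no headline skill metrics are reported for profiles, because observation
depths and layer depths do not coincide and samples are small. The deepest
observation may legitimately exceed the deepest modelled layer (bathymetry
unresolved by the mesh); this never errors.

## Variability diagnostics

For a node set of interest (default: nodes with observations): median
absolute seabed-temperature difference to mesh neighbours over all hours;
median absolute hour-to-hour change; the site-wide median (over hours) of
the across-node IQR; median and maximum within-day range; and the median
absolute hourly change of seabed-layer depth, |σ̃_L|·|Δζ|. The first two
sitting far below the 0.1 °C tag accuracy is the quantitative justification
for nearest node-and-hour pairing.

## Problem sizes and determinism

The default configuration (150 nodes, 10 layers, hourly fields over
2016-03-15 – 2017-06-01, three individuals, 12 receivers, 8 angling events,
1,000 ensemble replicates) yields ≈10,000 node-hour validation rows and runs
in well under a minute on one CPU; the test suite uses the same conditions
with two individuals. All sub-streams (mesh, fields, per-animal tracks, tags,
detections, events, each ensemble) derive from one master seed via a seed
sequence, and every numeric output file reproduces byte-identically under a
fixed config.

## Limitations

The generator does not emulate: behaviourally realistic movement (no habitat
preference, burial, or off-bottom excursions — the benthic assumption is
exact by construction, so these tests cannot probe its violation); spatially
structured model error (bias is piecewise-constant, so spatial skill
variation among nodes is nearly absent and depth regressions are expected to
find nothing); receiver deployment gaps; tag clock drift; or vessel drift
during ascents. Consequently, passing the parameter-recovery experiments
demonstrates the pipeline's statistical machinery is unbiased and correctly
seeded — not that a real model's error structure satisfies these simplifying
assumptions.
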