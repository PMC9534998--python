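"""Synthetic study system: mesh, temperature fields with a known model bias,
benthic tracks, archival tag records, acoustic detections and angling events.

Everything downstream of the real study's data acquisition is testable against
this generator because the model-minus-truth offset (the "bias schedule") is
known exactly: the model field is the truth field plus the schedule, and tag
records are the truth field seen through the tag's accuracy and resolution.

Tag characteristics default to the Star-Oddi Milli-TD archival tag
(temperature resolution 0.032 degC / accuracy 0.1 degC; depth resolution
0.24 m / accuracy 4.77 m; one record every 120 s) and to a 69 kHz acoustic
system with detection probability 0.5 at 425 m and a ~60 s randomised
transmission delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.spatial import Delaunay

from .meshfield import FieldSeries, Mesh, SigmaScheme, nearest_nodes

__all__ = [
    "TagSpec",
    "DetectionModel",
    "BiasRule",
    "BiasSchedule",
    "TruthAndModel",
    "generate_mesh",
    "generate_fields",
    "simulate_track",
    "sample_archival",
    "simulate_detections",
    "simulate_angling",
    "place_receivers",
    "detection_area_km2",
]

SHALLOW_CUTOFF_M = 50.0  # shallow (< 50 m) vs deep (>= 50 m) water


@dataclass(frozen=True)
class TagSpec:
    """Archival tag sampling characteristics (manufacturer specification)."""

    sample_interval_s: float = 120.0
    temp_resolution: float = 0.032  # degC
    temp_accuracy_sd: float = 0.1  # degC
    depth_resolution: float = 0.24  # m
    depth_accuracy_sd: float = 4.77  # m

    def __post_init__(self) -> None:
        for name in ("sample_interval_s", "temp_resolution", "temp_accuracy_sd",
                     "depth_resolution", "depth_accuracy_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.temp_resolution > max(self.temp_accuracy_sd, 1e-12) and self.temp_accuracy_sd > 0:
            raise ValueError("temperature resolution exceeds accuracy")


@dataclass(frozen=True)
class DetectionModel:
    """Logistic detection-probability curve plus transmission timing.

    ``range_p50`` is the distance at which detection probability is 0.5; the
    curve is p(dist) = 1 / (1 + exp((dist - range_p50) / logistic_scale)).
    False detections are injected as isolated single events at ``false_rate``
    per receiver-day (the failure mode the short-interval filter targets).
    """

    range_p50: float = 425.0  # m
    logistic_scale: float = 60.0  # m
    nominal_delay_s: float = 60.0
    delay_jitter_s: float = 15.0  # uniform half-width
    false_rate_per_day: float = 2.0

    def probability(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return 1.0 / (1.0 + np.exp((d - self.range_p50) / self.logistic_scale))


def detection_area_km2(model: DetectionModel | None = None) -> float:
    """Area (km^2) surveyed by one receiver, pi * r^2 at the 0.5-probability range."""
    r_km = (model.range_p50 if model is not None else 425.0) / 1000.0
    return float(np.pi * r_km**2)


@dataclass(frozen=True)
class BiasRule:
    """Additive model-minus-truth offset over a period and depth class."""

    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    value: float  # degC
    depth_class: str | None = None  # None, "shallow" or "deep"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not np.isfinite(self.value):
            raise ValueError("bias value must be finite")
        if self.depth_class not in (None, "shallow", "deep"):
            raise ValueError("depth_class must be None, 'shallow' or 'deep'")


@dataclass(frozen=True)
class BiasSchedule:
    """Piecewise-constant b(t, node): sum of all rules matching (time, depth class)."""

    rules: tuple[BiasRule, ...] = ()

    @classmethod
    def constant(cls, value: float) -> "BiasSchedule":
        return cls((BiasRule(pd.Timestamp.min, pd.Timestamp.max, value),))

    @classmethod
    def two_period(
        cls,
        switch: str | pd.Timestamp = "2017-01-01",
        before: float = 0.53,
        after: float = -0.045,
    ) -> "BiasSchedule":
        """Default schedule emulating a model update: a consistent warm bias
        before the switch date and a small residual cool bias after it."""
        switch = pd.Timestamp(switch)
        return cls(
            (
                BiasRule(pd.Timestamp.min, switch, before),
                BiasRule(switch, pd.Timestamp.max, after),
            )
        )

    def offsets(self, hours: pd.DatetimeIndex, mesh: Mesh) -> np.ndarray:
        """(time, node) additive offsets in degC."""
        out = np.zeros((len(hours), mesh.n_nodes))
        shallow = mesh.h < SHALLOW_CUTOFF_M
        for rule in self.rules:
            in_t = (hours >= rule.start) & (hours < rule.end)
            if rule.depth_class is None:
                node_mask = np.ones(mesh.n_nodes, dtype=bool)
            elif rule.depth_class == "shallow":
                node_mask = shallow
            else:
                node_mask = ~shallow
            out[np.ix_(np.asarray(in_t), node_mask)] += rule.value
        return out


@dataclass
class TruthAndModel:
    """A truth field and the model field (truth + bias schedule)."""

    truth: FieldSeries
    model: FieldSeries
    schedule: BiasSchedule


# ---------------------------------------------------------------------------
# mesh


def generate_mesh(
    extent: tuple[float, float] = (20_000.0, 20_000.0),
    n_nodes: int = 150,
    depth_range: tuple[float, float] = (5.0, 290.0),
    n_layers: int = 10,
    seed: int = 0,
) -> tuple[Mesh, SigmaScheme]:
    """Delaunay-triangulated planar mesh with smooth basin-and-platform bathymetry.

    The rectangle boundary (corners plus perimeter points) is always included
    so the mesh hull is exactly the extent rectangle.  Bathymetry is a sum of
    Gaussian basins over a sloping base, clipped to ``depth_range``.
    """
    w, hgt = float(extent[0]), float(extent[1])
    if w <= 0 or hgt <= 0:
        raise ValueError("degenerate extent")
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = np.random.default_rng(seed)

    n_side = 5
    bx = np.linspace(0, w, n_side)
    by = np.linspace(0, hgt, n_side)
    boundary = np.unique(
        np.concatenate(
            [
                np.column_stack([bx, np.zeros(n_side)]),
                np.column_stack([bx, np.full(n_side, hgt)]),
                np.column_stack([np.zeros(n_side), by]),
                np.column_stack([np.full(n_side, w), by]),
            ]
        ),
        axis=0,
    )
    n_interior = max(n_nodes - boundary.shape[0], 4)
    interior = np.column_stack(
        [rng.uniform(0.02 * w, 0.98 * w, n_interior), rng.uniform(0.02 * hgt, 0.98 * hgt, n_interior)]
    )
    pts = np.concatenate([boundary, interior])

    tri = Delaunay(pts)
    node_ids = np.arange(pts.shape[0], dtype=np.int64)

    # bathymetry: sloping base + random Gaussian basins/platforms, rescaled to
    # span depth_range exactly (no clipping plateaus)
    lo, hi = depth_range
    relief = 0.3 * (pts[:, 0] / w + pts[:, 1] / hgt) / 2
    for _ in range(6):
        cx, cy = rng.uniform(0, w), rng.uniform(0, hgt)
        amp = rng.uniform(-0.9, 0.9)
        scale = rng.uniform(0.1, 0.3) * max(w, hgt)
        relief += amp * np.exp(-(((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2) / (2 * scale**2)))
    depth = lo + (hi - lo) * (relief - relief.min()) / max(np.ptp(relief), 1e-12)

    mesh = Mesh(node_ids=node_ids, x=pts[:, 0], y=pts[:, 1], h=depth, elements=node_ids[tri.simplices])
    return mesh, SigmaScheme.uniform(n_layers)


# ---------------------------------------------------------------------------
# fields


def generate_fields(
    mesh: Mesh,
    scheme: SigmaScheme,
    start="2016-03-15",
    end="2017-06-01",
    seasonal_min: float = 6.0,
    seasonal_max: float = 16.0,
    seasonal_peak_doy: float = 227.0,  # mid-August
    strat_magnitude: float = 1.5,  # degC surface-to-seabed contrast at peak
    strat_peak_doy: float = 205.0,
    strat_width_days: float = 60.0,
    spatial_amplitude: float = 0.2,  # degC across the domain
    ar_sd: float = 0.05,
    ar_phi: float = 0.8,
    tide_amplitude: float = 0.8,  # m
    bias: BiasSchedule | None = None,
    seed: int = 0,
) -> TruthAndModel:
    """Hourly truth field plus model field (truth + bias schedule).

    Truth combines a sinusoidal seasonal cycle spanning roughly
    [seasonal_min, seasonal_max], a summer-only linear-in-sigma thermal
    stratification (surface warmer than seabed, Gaussian seasonal envelope), a
    small smooth spatial gradient and a site-wide AR(1) hourly anomaly.  Tidal
    elevation is an M2-like sinusoid shared by truth and model.
    """
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    if len(hours) < 24:
        raise ValueError("span must cover at least one day")
    rng = np.random.default_rng(seed)
    if bias is None:
        bias = BiasSchedule.two_period()

    doy = hours.dayofyear.values + hours.hour.values / 24.0
    mid = 0.5 * (seasonal_min + seasonal_max)
    amp = 0.5 * (seasonal_max - seasonal_min)
    seasonal = mid + amp * np.cos(2 * np.pi * (doy - seasonal_peak_doy) / 365.25)

    # spatial gradient, normalised to +-spatial_amplitude/2 across the domain
    gx = (mesh.x - mesh.x.mean()) / max(np.ptp(mesh.x), 1.0)
    gy = (mesh.y - mesh.y.mean()) / max(np.ptp(mesh.y), 1.0)
    spatial = spatial_amplitude * 0.5 * (gx + gy)

    # stratification profile: full magnitude at the surface layer, zero at the
    # seabed layer, linear in |sigma| between
    c = np.abs(scheme.layer_centres)
    profile = (c[-1] - c) / (c[-1] - c[0])
    envelope = np.exp(-(((doy - strat_peak_doy) / strat_width_days) ** 2))
    strat = strat_magnitude * envelope[:, None] * profile[None, :]  # (T, L)

    innov = rng.normal(0.0, ar_sd * np.sqrt(1 - ar_phi**2), len(hours))
    anomaly = lfilter([1.0], [1.0, -ar_phi], innov)

    truth_temp = (
        seasonal[:, None, None]
        + spatial[None, :, None]
        + strat[:, None, :]
        + anomaly[:, None, None]
    )

    t_h = (hours - hours[0]).total_seconds().values / 3600.0
    phase = 2 * np.pi * (mesh.x - mesh.x.min()) / max(np.ptp(mesh.x), 1.0) * 0.05
    zeta = tide_amplitude * np.sin(2 * np.pi * t_h[:, None] / 12.42 + phase[None, :])

    truth = FieldSeries(hours=hours, temp=truth_temp, zeta=zeta)
    model = FieldSeries(
        hours=hours, temp=truth_temp + bias.offsets(hours, mesh)[:, :, None], zeta=zeta
    )
    return TruthAndModel(truth=truth, model=model, schedule=bias)


# ---------------------------------------------------------------------------
# movement


def simulate_track(
    mesh: Mesh,
    start="2016-03-15",
    end="2017-06-01",
    dt_s: float = 120.0,
    step_sd: float = 30.0,  # m per step
    home: tuple[float, float] | None = None,
    home_strength: float = 1e-3,  # mean-reversion per step
    max_offset: float = 0.5,  # m swum above the seabed
    seed: int = 0,
) -> pd.DataFrame:
    """Benthic random-walk track inside the mesh hull.

    A mean-reverting (home-ranging) walk reflected at the hull boundary; the
    animal's depth is the local seabed depth (bathymetry at the nearest node)
    minus a small non-negative offset.  Columns: timestamp, x, y, node_id,
    seabed_m, depth_m.
    """
    times = pd.date_range(start, end, freq=pd.Timedelta(seconds=dt_s), inclusive="left")
    if len(times) < 3600 / dt_s:
        raise ValueError("track must span at least one hour")
    rng = np.random.default_rng(seed)
    if home is None:
        home = (float(mesh.x.mean()), float(mesh.y.mean()))

    n = len(times)
    rho = 1.0 - home_strength
    dev = np.column_stack(
        [
            lfilter([1.0], [1.0, -rho], rng.normal(0.0, step_sd, n)),
            lfilter([1.0], [1.0, -rho], rng.normal(0.0, step_sd, n)),
        ]
    )
    pos = np.asarray(home, dtype=float) + dev

    # reflect into the mesh bounding rectangle (the hull, by construction)
    for axis, (lo, hi) in enumerate(
        [(mesh.x.min(), mesh.x.max()), (mesh.y.min(), mesh.y.max())]
    ):
        width = hi - lo
        y = np.mod(pos[:, axis] - lo, 2 * width)
        pos[:, axis] = lo + (width - np.abs(y - width))

    node = nearest_nodes(pos, mesh)
    seabed = mesh.h[mesh.index_of(node)]
    offset = rng.uniform(0.0, max_offset, n) if max_offset > 0 else np.zeros(n)
    return pd.DataFrame(
        {
            "timestamp": times,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "node_id": node,
            "seabed_m": seabed,
            "depth_m": np.maximum(seabed - offset, 0.0),
        }
    )


# ---------------------------------------------------------------------------
# tag sampling


def _quantize(values: np.ndarray, resolution: float) -> np.ndarray:
    if resolution <= 0:
        return values
    return np.round(values / resolution) * resolution


def _hour_index(hours: pd.DatetimeIndex, when: pd.DatetimeIndex) -> np.ndarray:
    """Vectorised nearest-hour index; errors if outside coverage (+-30 min)."""
    rel = np.asarray((when - hours[0]).total_seconds() / 3600.0)
    # times inside the final covered hour (up to hours[-1] + 1 h) snap down
    if rel.min() < -0.5 or rel.max() >= len(hours):
        raise ValueError("track extends outside the field time span")
    return np.clip(np.round(rel).astype(np.int64), 0, len(hours) - 1)


def sample_archival(
    track: pd.DataFrame,
    truth: FieldSeries,
    mesh: Mesh,
    spec: TagSpec = TagSpec(),
    individual_id: str = "skate-1",
    seed: int = 0,
) -> pd.DataFrame:
    """Archival tag records along a track: quantised, noisy truth temperatures.

    The animal experiences the seabed-layer truth temperature at its nearest
    node and hour (benthic assumption); the tag reports that value through
    Gaussian sensor noise (accuracy) and quantisation (resolution), likewise
    for depth.  Columns: timestamp, individual_id, depth_m, temp_c.
    """
    rng = np.random.default_rng(seed)
    times = pd.DatetimeIndex(track["timestamp"])
    t_idx = _hour_index(truth.hours, times)
    n_idx = mesh.index_of(track["node_id"].values)
    temp_true = truth.bottom()[t_idx, n_idx]
    temp = _quantize(temp_true + rng.normal(0.0, spec.temp_accuracy_sd, len(times)),
                     spec.temp_resolution)
    depth = _quantize(
        track["depth_m"].values + rng.normal(0.0, spec.depth_accuracy_sd, len(times)),
        spec.depth_resolution,
    )
    return pd.DataFrame(
        {
            "timestamp": times,
            "individual_id": individual_id,
            "depth_m": np.maximum(depth, 0.0),
            "temp_c": temp,
        }
    ).sort_values("timestamp", ignore_index=True)


# ---------------------------------------------------------------------------
# acoustic detections


def simulate_detections(
    track: pd.DataFrame,
    receivers: pd.DataFrame,
    model: DetectionModel = DetectionModel(),
    transmitter_id: str = "skate-1",
    false_ids: tuple[str, ...] | None = None,
    seed: int = 0,
    chunk: int = 100_000,
) -> pd.DataFrame:
    """Acoustic detections of a transmitting track at moored receivers.

    Transmissions occur at the nominal delay plus uniform jitter (so spacing
    never falls below nominal - jitter); each is heard independently by each
    receiver with logistic probability of distance.  False detections are
    injected as isolated singletons of phantom transmitter codes at
    ``false_rate_per_day`` per receiver; the ``is_false`` column is generator
    ground truth, not information available to the analysis.
    """
    if receivers.empty:
        raise ValueError("receivers table is empty")
    if false_ids is None:
        # decode errors yield essentially arbitrary codes, so falses land on
        # many phantom ids and stay isolated (no accidental companions)
        false_ids = tuple(f"ghost-{k:02d}" for k in range(50))
    rng = np.random.default_rng(seed)
    times = pd.DatetimeIndex(track["timestamp"])
    t0, t1 = times[0], times[-1]
    span_s = (t1 - t0).total_seconds()

    n_tx = int(span_s / max(model.nominal_delay_s - model.delay_jitter_s, 1e-9)) + 2
    gaps = model.nominal_delay_s + rng.uniform(-model.delay_jitter_s, model.delay_jitter_s, n_tx)
    tx_s = np.cumsum(gaps)
    tx_s = tx_s[tx_s < span_s]

    track_s = (times - t0).total_seconds().values
    tx_x = np.interp(tx_s, track_s, track["x"].values)
    tx_y = np.interp(tx_s, track_s, track["y"].values)

    rec_x = receivers["x"].values
    rec_y = receivers["y"].values
    rec_ids = receivers["receiver_id"].values

    out_t, out_r = [], []
    for lo in range(0, tx_s.size, chunk):
        sl = slice(lo, lo + chunk)
        d = np.hypot(tx_x[sl][:, None] - rec_x, tx_y[sl][:, None] - rec_y)
        heard = rng.random(d.shape) < model.probability(d)
        ti, ri = np.nonzero(heard)
        out_t.append(tx_s[sl][ti])
        out_r.append(ri)
    det_s = np.concatenate(out_t) if out_t else np.array([])
    det_r = np.concatenate(out_r) if out_r else np.array([], dtype=int)

    frames = [
        pd.DataFrame(
            {
                "timestamp": t0 + pd.to_timedelta(det_s, unit="s"),
                "receiver_id": rec_ids[det_r],
                "transmitter_id": transmitter_id,
                "is_false": False,
            }
        )
    ]
    if model.false_rate_per_day > 0:
        days = span_s / 86400.0
        for rid in rec_ids:
            k = rng.poisson(model.false_rate_per_day * days)
            if k == 0:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": t0 + pd.to_timedelta(rng.uniform(0, span_s, k), unit="s"),
                        "receiver_id": rid,
                        "transmitter_id": rng.choice(list(false_ids), k),
                        "is_false": True,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True).sort_values("timestamp", ignore_index=True)


def place_receivers(
    mesh: Mesh, centre: tuple[float, float] | None = None, n: int = 12, prefix: str = "R"
) -> pd.DataFrame:
    """Receivers at the ``n`` mesh nodes nearest a centre point (colocated with nodes)."""
    if centre is None:
        centre = (float(mesh.x.mean()), float(mesh.y.mean()))
    d2 = (mesh.x - centre[0]) ** 2 + (mesh.y - centre[1]) ** 2
    pick = np.argsort(d2)[:n]
    return pd.DataFrame(
        {
            "receiver_id": [f"{prefix}{i:02d}" for i in range(len(pick))],
            "x": mesh.x[pick],
            "y": mesh.y[pick],
        }
    )


# ---------------------------------------------------------------------------
# angling events


def simulate_angling(
    track: pd.DataFrame,
    archival: pd.DataFrame,
    truth: FieldSeries,
    mesh: Mesh,
    scheme: SigmaScheme,
    spec: TagSpec = TagSpec(),
    n_events: int = 8,
    duration_range_min: tuple[float, float] = (8.0, 20.0),
    surface_depth: float = 0.3,
    min_event_depth: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Capture ascents written into an archival series, plus the event log.

    Each event pulls the animal from its seabed depth to the surface over a
    duration drawn uniformly from ``duration_range_min``; ascent temperatures
    are the truth temperature of the sigma layer containing the instantaneous
    depth.  Ascent depths carry resolution-scale noise with a monotone trend
    (pressure-sensor short-term precision is near the resolution; the 4.77 m
    accuracy figure is an absolute calibration bound).  The final event is a
    tag-retrieval event, the others occur at liberty.

    Returns ``(events, archival_with_ascents)``; the input archival frame is
    not modified.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    arch = archival.copy()
    times = pd.DatetimeIndex(arch["timestamp"])
    dt = pd.Timedelta(seconds=spec.sample_interval_s)
    max_steps = int(np.ceil(duration_range_min[1] * 60 / spec.sample_interval_s)) + 1
    if len(times) < (n_events + 1) * (max_steps + 5):
        raise ValueError("archival series too short for the requested events")

    # anglers target deep water, and an ascent is only distinguishable from
    # tag depth noise when the seabed lies well below the surface: anchor
    # events at times when the animal is in deep enough water
    track_times = pd.DatetimeIndex(track["timestamp"])
    # keep an hour clear of both ends so event hours stay inside field coverage
    margin = max(int(3600 / spec.sample_interval_s), 1)
    usable = np.arange(margin, len(times) - max_steps - margin)
    deep = usable[track["depth_m"].values[np.minimum(usable, len(track) - 1)] >= min_event_depth]
    if deep.size < n_events:
        order = np.argsort(-track["depth_m"].values[np.minimum(usable, len(track) - 1)])
        deep = np.sort(usable[order[: max(n_events * 10, 100)]])
    sep = max_steps + 5
    anchors = []
    prev = -sep
    for target in deep[np.linspace(0, deep.size - 1, n_events).astype(int)]:
        cands = deep[deep >= max(int(target), prev + sep)]
        if cands.size == 0:
            cands = deep[deep >= prev + sep]
        if cands.size == 0:
            raise ValueError("track spends too little time in deep water "
                             "for the requested number of events")
        prev = int(cands[0])
        anchors.append(prev)
    events = []
    for e, a0 in enumerate(anchors):
        t_start = times[a0]
        dur_min = rng.uniform(*duration_range_min)
        n_steps = max(int(np.ceil(dur_min * 60 / spec.sample_interval_s)), 3)

        ti = track_times.get_indexer([t_start], method="nearest")[0]
        d0 = float(track["depth_m"].iloc[ti])
        x0, y0 = float(track["x"].iloc[ti]), float(track["y"].iloc[ti])
        node = int(track["node_id"].iloc[ti])

        frac = np.arange(1, n_steps + 1) / n_steps
        depths = d0 * (1 - frac) + rng.normal(0.0, spec.depth_resolution / 2, n_steps)
        depths = np.minimum.accumulate(np.maximum(depths, 0.0))
        depths[-1] = min(depths[-1], rng.uniform(0.0, surface_depth))
        depths = _quantize(depths, spec.depth_resolution)

        # layer containing each instantaneous depth, at the event node/hour
        h_node = float(mesh.h[mesh.index_of(np.int64(node))])
        ascent_times = t_start + dt * np.arange(1, n_steps + 1)
        t_idx = _hour_index(truth.hours, pd.DatetimeIndex(ascent_times))
        n_idx = int(mesh.index_of(np.int64(node)))
        temps = np.empty(n_steps)
        for j in range(n_steps):
            zeta = truth.zeta[t_idx[j], n_idx]
            bounds = np.abs(scheme.sigma_levels[1:]) * (h_node + zeta)
            layer = min(int(np.searchsorted(bounds, depths[j])), scheme.n_layers - 1)
            temps[j] = truth.temp[t_idx[j], n_idx, layer]
        temps = _quantize(temps + rng.normal(0.0, spec.temp_accuracy_sd, n_steps),
                          spec.temp_resolution)

        sel = arch.index[(times > t_start) & (times <= ascent_times[-1])]
        arch.loc[sel, "depth_m"] = depths[: len(sel)]
        arch.loc[sel, "temp_c"] = temps[: len(sel)]

        events.append(
            {
                "individual_id": arch["individual_id"].iloc[0],
                "event_time": t_start,
                "x": x0,
                "y": y0,
                "event_type": "retrieval" if e == n_events - 1 else "liberty",
                "drawn_duration_min": dur_min,
            }
        )
    return pd.DataFrame(events), arch
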