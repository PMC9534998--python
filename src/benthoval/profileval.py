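"""Temperature-depth profile validation from capture (angling) ascents.

When a tagged animal is hooked and pulled to the surface, its archival tag
samples a vertical temperature-depth profile of the water column.  Each event
is defined from the last depth observation preceding the ascent (C) to the
first observation at the surface (S); the observed profile is paired with the
modelled sigma-layer profile at the nearest node and the hour nearest the
event start, with layer depths computed from the tidal elevation at that hour.

Profiles are visual/diagnostic evidence only: the mismatch between observation
depths and sigma-layer depths, and the small sample, make headline skill
metrics inappropriate here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshfield import FieldSeries, Mesh, SigmaScheme, layer_depths, nearest_node, snap_hour
from .synthdata import TagSpec

__all__ = ["AnglingEvent", "ProfilePair", "extract_ascent", "model_profile", "pair_profile"]


@dataclass(frozen=True)
class AnglingEvent:
    """A capture ascent: from seabed departure (C) to first surface record (S)."""

    individual_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    x: float
    y: float
    event_type: str  # "liberty" or "retrieval"
    node_id: int | None = None

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must precede end")
        if self.event_type not in ("liberty", "retrieval"):
            raise ValueError("event_type must be 'liberty' or 'retrieval'")


@dataclass
class ProfilePair:
    """Modelled sigma-layer profile paired with the observed ascent records.

    ``modelled`` columns: layer, depth_m, temp_c.  ``observed`` columns:
    timestamp, depth_m, temp_c, depth_err_m, temp_err_c (the +-accuracy
    uncertainty of the tag).  ``diagnostics`` holds per-layer differences to
    the nearest observation by depth — a diagnostic, not a skill score.
    """

    event: AnglingEvent
    modelled: pd.DataFrame
    observed: pd.DataFrame
    zeta_used: float
    diagnostics: pd.DataFrame | None = None


def extract_ascent(
    archival: pd.DataFrame,
    capture_time,
    surface_threshold: float = 1.0,
    search_window: pd.Timedelta = pd.Timedelta(hours=2),
    tolerance: float = 0.24,
    min_run: int = 3,
    event_type: str = "retrieval",
    location: tuple[float, float] = (np.nan, np.nan),
) -> AnglingEvent:
    """Locate a capture ascent in one individual's archival series.

    Scans ``+-search_window`` around ``capture_time`` (an angler-reported
    capture record) for the first record at or above ``surface_threshold``
    depth, then walks backwards through the run of records whose depth
    increases (backwards in time) within ``tolerance`` of monotone; the run's
    first record is the last observation preceding the ascent.
    """
    arch = archival.sort_values("timestamp", kind="stable").reset_index(drop=True)
    t = pd.DatetimeIndex(arch["timestamp"])
    capture_time = pd.Timestamp(capture_time)
    in_win = (t >= capture_time - search_window) & (t <= capture_time + search_window)
    if not in_win.any():
        raise ValueError(f"no archival records within {search_window} of {capture_time}")
    win = arch.loc[in_win]
    surf = win.index[win["depth_m"] <= surface_threshold]
    if len(surf) == 0:
        raise ValueError(
            f"no surface record (depth <= {surface_threshold} m) within "
            f"{search_window} of {capture_time}"
        )
    s = int(surf[0])  # first observation at the surface
    depths = arch["depth_m"].values
    # walk back while depth keeps rising (backwards in time) by more than the
    # tolerance; a single stalled/small-reversal record is kept only when the
    # record before it resumes the ascent, so flat pre-event runs end the walk
    c = s
    while c > 0:
        step = depths[c - 1] - depths[c]
        if step > tolerance:
            c -= 1
        elif step >= -tolerance and c > 1 and depths[c - 2] - depths[c - 1] > tolerance:
            c -= 2
        else:
            break
    if s - c + 1 < min_run:
        raise ValueError("no monotone ascent run of at least "
                         f"{min_run} records ending at {t[s]}")
    return AnglingEvent(
        individual_id=str(arch["individual_id"].iloc[0]),
        start=t[c],
        end=t[s],
        x=float(location[0]),
        y=float(location[1]),
        event_type=event_type,
    )


def model_profile(
    fields: FieldSeries,
    mesh: Mesh,
    scheme: SigmaScheme,
    event: AnglingEvent,
) -> tuple[pd.DataFrame, float, int]:
    """Modelled per-layer (depth, temperature) at the event node and start hour.

    The node is the mesh node nearest the event location (or ``event.node_id``
    if set); the hour is the grid hour nearest the event *start*; layer depths
    use the tidal elevation at that hour.  Returns (profile, zeta, node_id).
    """
    node = event.node_id
    if node is None:
        if not np.isfinite(event.x) or not np.isfinite(event.y):
            raise ValueError("event has neither a node_id nor a finite location")
        node = nearest_node((event.x, event.y), mesh)
    t = snap_hour(fields.hours, event.start)
    n = int(mesh.index_of(np.int64(node)))
    zeta = float(fields.zeta[t, n])
    depths = layer_depths(scheme, float(mesh.h[n]), zeta)
    profile = pd.DataFrame(
        {
            "layer": np.arange(1, scheme.n_layers + 1),
            "depth_m": depths,
            "temp_c": fields.temp[t, n, :],
        }
    )
    return profile, zeta, int(node)


def pair_profile(
    event: AnglingEvent,
    archival: pd.DataFrame,
    modelled: pd.DataFrame,
    spec: TagSpec = TagSpec(),
    zeta_used: float = 0.0,
    with_diagnostics: bool = True,
) -> ProfilePair:
    """Pair the observed ascent records with the modelled layer profile.

    Observed records in ``[start, end]`` carry the tag's accuracy as symmetric
    uncertainty (depth +- 4.77 m, temperature +- 0.1 degC by default).  The
    deepest observation may lie below the deepest modelled layer (unresolved
    local bathymetry); that is expected and does not raise.
    """
    arch = archival.loc[
        (archival["individual_id"] == event.individual_id)
        & (archival["timestamp"] >= event.start)
        & (archival["timestamp"] <= event.end)
    ]
    if len(arch) < 2:
        raise ValueError("need at least 2 observed records inside the event window")
    observed = pd.DataFrame(
        {
            "timestamp": arch["timestamp"].values,
            "depth_m": arch["depth_m"].values,
            "temp_c": arch["temp_c"].values,
            "depth_err_m": spec.depth_accuracy_sd,
            "temp_err_c": spec.temp_accuracy_sd,
        }
    )
    diagnostics = None
    if with_diagnostics:
        oi = np.argmin(
            np.abs(modelled["depth_m"].values[:, None] - observed["depth_m"].values[None, :]),
            axis=1,
        )
        diagnostics = pd.DataFrame(
            {
                "layer": modelled["layer"].values,
                "layer_depth_m": modelled["depth_m"].values,
                "nearest_obs_depth_m": observed["depth_m"].values[oi],
                "diff_c": modelled["temp_c"].values - observed["temp_c"].values[oi],
            }
        )
    return ProfilePair(
        event=event, modelled=modelled, observed=observed,
        zeta_used=zeta_used, diagnostics=diagnostics,
    )
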