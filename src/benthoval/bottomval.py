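"""Node-hour bottom-temperature validation dataset and validation effort.

Archival temperature records are usable for validation only while the animal's
location is known from a simultaneous acoustic detection.  Linked records are
averaged per (node, calendar hour) and paired with the modelled seabed-layer
temperature at the same node and hour, giving one validation row per node-hour
with diff = modelled - observed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .meshfield import FieldSeries, Mesh, snap_hour
from .synthdata import SHALLOW_CUTOFF_M

__all__ = ["link_archival_to_detections", "build_validation_dataset", "effort_summary"]

_SEASONS = {12: "winter", 1: "winter", 2: "winter", 3: "spring", 4: "spring", 5: "spring",
            6: "summer", 7: "summer", 8: "summer", 9: "autumn", 10: "autumn", 11: "autumn"}


def link_archival_to_detections(
    archival: pd.DataFrame,
    detections: pd.DataFrame,
    max_gap: pd.Timedelta = pd.Timedelta(minutes=30),
    require_same_hour: bool = True,
    transmitter_of: dict | None = None,
) -> pd.DataFrame:
    """Annotate archival records with the node of the nearest valid detection.

    For each individual, every archival record is matched to the temporally
    nearest detection of its transmitter; the match stands only if the gap is
    within ``max_gap`` and (by default) both fall in the same calendar hour.
    Unmatched records are dropped.  ``transmitter_of`` maps individual id to
    transmitter id (identity by default).
    """
    det = detections.copy()
    if transmitter_of:
        inv = {v: k for k, v in transmitter_of.items()}
        det["individual_id"] = det["transmitter_id"].map(inv)
    else:
        det["individual_id"] = det["transmitter_id"]

    shared = set(archival["individual_id"]) & set(det["individual_id"])
    if not shared:
        import warnings

        warnings.warn("archival and detections share no individual ids", stacklevel=2)
        return archival.iloc[0:0].assign(node_id=np.array([], dtype=np.int64),
                                         node_depth_m=np.array([], dtype=float))

    arch = archival.sort_values("timestamp", kind="stable").reset_index(drop=True)
    det = det.sort_values("timestamp", kind="stable").reset_index(drop=True)
    linked = pd.merge_asof(
        arch,
        det[["timestamp", "individual_id", "node_id", "node_depth_m"]].rename(
            columns={"timestamp": "det_time"}
        ),
        left_on="timestamp",
        right_on="det_time",
        by="individual_id",
        direction="nearest",
        tolerance=max_gap,
    )
    linked = linked.dropna(subset=["node_id"])
    if require_same_hour:
        same = linked["timestamp"].dt.floor("h") == linked["det_time"].dt.floor("h")
        linked = linked.loc[same]
    linked = linked.astype({"node_id": np.int64})
    return linked.drop(columns=["det_time"]).reset_index(drop=True)


def build_validation_dataset(
    linked: pd.DataFrame, fields: FieldSeries, mesh: Mesh
) -> pd.DataFrame:
    """One row per (node, hour): mean observed vs modelled seabed temperature.

    The hour bin is the UTC calendar hour containing the record timestamp.
    Modelled temperature is the seabed-layer value at that node and hour.
    Raises if the field series does not cover every required hour.
    """
    if linked.empty:
        raise ValueError("no linked archival records")
    df = linked.copy()
    df["hour"] = df["timestamp"].dt.floor("h")
    grouped = (
        df.groupby(["node_id", "hour"], sort=False)
        .agg(n_records=("temp_c", "size"), obs_temp=("temp_c", "mean"),
             node_depth_m=("node_depth_m", "first"))
        .reset_index()
        .sort_values(["hour", "node_id"], ignore_index=True)
    )

    missing = [h for h in pd.DatetimeIndex(grouped["hour"].unique())
               if not (fields.hours[0] <= h <= fields.hours[-1])]
    if missing:
        raise ValueError(f"field coverage missing for hours: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))

    t_of = {h: snap_hour(fields.hours, h) for h in pd.DatetimeIndex(grouped["hour"].unique())}
    t_idx = grouped["hour"].map(t_of).to_numpy(dtype=np.int64)
    n_idx = mesh.index_of(grouped["node_id"].values)
    grouped["mod_temp"] = fields.bottom()[t_idx, n_idx]
    grouped["diff"] = grouped["mod_temp"] - grouped["obs_temp"]
    grouped["depth_class"] = np.where(grouped["node_depth_m"] < SHALLOW_CUTOFF_M, "shallow", "deep")
    grouped["year"] = grouped["hour"].dt.year
    grouped["month"] = grouped["hour"].dt.month
    grouped["season"] = grouped["month"].map(_SEASONS)
    cols = ["node_id", "hour", "n_records", "obs_temp", "mod_temp", "diff",
            "node_depth_m", "depth_class", "month", "year", "season"]
    return grouped[cols]


def effort_summary(validation: pd.DataFrame) -> dict:
    """Validation effort through time and space.

    Returns observations per day, per-node counts and percentages, the number
    of nodes with observations per hour plus its weekly mean, per-depth-class
    counts, the span in days and the number of days without observations.
    """
    if validation.empty:
        raise ValueError("empty validation table")
    vt = validation.copy()
    day = vt["hour"].dt.floor("D")
    obs_per_day = vt.groupby(day).size().rename("n_obs")
    full_days = pd.date_range(day.min(), day.max(), freq="D")
    obs_per_day = obs_per_day.reindex(full_days, fill_value=0)

    per_node = vt.groupby("node_id").size().rename("n_obs").reset_index()
    per_node["pct"] = 100.0 * per_node["n_obs"] / per_node["n_obs"].sum()

    nodes_per_hour = vt.groupby("hour")["node_id"].nunique().rename("n_nodes")
    weekly_mean = nodes_per_hour.resample("7D").mean().rename("weekly_mean_nodes")

    return {
        "obs_per_day": obs_per_day,
        "obs_per_node": per_node,
        "nodes_per_hour": nodes_per_hour,
        "nodes_weekly_mean": weekly_mean,
        "obs_per_depth_class": vt.groupby("depth_class").size(),
        "span_days": int(len(full_days)),
        "gap_days": int((obs_per_day == 0).sum()),
        "n_obs": int(len(vt)),
        "n_nodes": int(vt["node_id"].nunique()),
    }
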