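"""Quality control of acoustic detections and localisation onto mesh nodes.

A detection localises the animal to within the detection range of a receiver
(~425 m here), so each valid detection is mapped to the mesh node nearest the
receiver. False detections — isolated code collisions — are removed with a
short-interval criterion: a detection is kept only if enough other detections
of the same transmitter occur nearby in time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .meshfield import Mesh, nearest_nodes

__all__ = ["short_interval_filter", "assign_nodes"]


def short_interval_filter(
    detections: pd.DataFrame,
    window: pd.Timedelta = pd.Timedelta(minutes=30),
    min_companions: int = 1,
    same_receiver: bool = True,
    return_report: bool = False,
):
    """Keep detections with >= ``min_companions`` companions within ``+-window``.

    Companions are other detections of the same transmitter (at the same
    receiver when ``same_receiver``).  With the default single-companion rule
    the companion relation is symmetric, so the filter is idempotent: no kept
    detection can lose its companions.  Row order and index are preserved.
    """
    if detections.empty:
        out = detections.copy()
        return (out, pd.DataFrame(columns=["receiver_id", "kept", "removed"])) if return_report else out

    keys = ["transmitter_id", "receiver_id"] if same_receiver else ["transmitter_id"]
    ts = pd.to_datetime(detections["timestamp"]).astype("int64")
    w = int(window.value)

    keep = np.zeros(len(detections), dtype=bool)
    grouped = pd.Series(np.arange(len(detections)), index=detections.index).groupby(
        [detections[k] for k in keys], sort=False
    )
    for _, rows in grouped:
        pos = rows.values
        pos = pos[np.argsort(ts.values[pos], kind="stable")]
        t = ts.values[pos]
        left = np.searchsorted(t, t - w, side="left")
        right = np.searchsorted(t, t + w, side="right")
        keep[pos] = (right - left - 1) >= min_companions

    out = detections.loc[keep]
    if not return_report:
        return out
    rep = (
        pd.DataFrame({"receiver_id": detections["receiver_id"], "kept": keep})
        .groupby("receiver_id")
        .agg(kept=("kept", "sum"), removed=("kept", lambda s: int((~s).sum())))
        .reset_index()
    )
    return out, rep


def assign_nodes(
    detections: pd.DataFrame, receivers: pd.DataFrame, mesh: Mesh
) -> pd.DataFrame:
    """Annotate detections with the mesh node (and its depth) nearest each receiver.

    Pure annotation: the row count is unchanged and several receivers may map
    to the same node.  Unknown receiver ids raise a ``KeyError`` naming them.
    """
    unknown = set(detections["receiver_id"]) - set(receivers["receiver_id"])
    if unknown:
        raise KeyError(f"unknown receiver id(s): {sorted(unknown)}")
    rec = receivers.copy()
    rec["node_id"] = nearest_nodes(rec[["x", "y"]].values, mesh)
    rec["node_depth_m"] = mesh.h[mesh.index_of(rec["node_id"].values)]
    return detections.merge(
        rec[["receiver_id", "node_id", "node_depth_m"]], on="receiver_id", how="left"
    ).set_index(detections.index)
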