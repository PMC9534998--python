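"""Figures regeneratable from the CSV outputs (never asserted on in tests)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["effort_figure", "profile_figure"]


def effort_figure(validation: pd.DataFrame, path) -> str:
    """Three-panel validation-effort figure: observations per day, per node,
    and nodes-with-observations per hour with its weekly mean."""
    vt = validation.copy()
    day = vt["hour"].dt.floor("D")
    fig, axes = plt.subplots(3, 1, figsize=(8, 9))

    obs_day = vt.groupby(day).size()
    axes[0].plot(obs_day.index, obs_day.values, lw=0.8, color="k")
    axes[0].set_ylabel("observations / day")

    per_node = vt.groupby("node_id").size().sort_values(ascending=False)
    axes[1].bar(range(len(per_node)), per_node.values, color="steelblue")
    axes[1].set_xlabel("node (ranked)")
    axes[1].set_ylabel("observations")

    nodes_hour = vt.groupby("hour")["node_id"].nunique()
    axes[2].plot(nodes_hour.index, nodes_hour.values, ".", ms=2, color="grey", alpha=0.4)
    weekly = nodes_hour.resample("7D").mean()
    axes[2].plot(weekly.index, weekly.values, "-o", ms=3, color="k")
    axes[2].set_ylabel("nodes with observations")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def profile_figure(pair, path) -> str:
    """Modelled vs observed temperature-depth profile with observation error bars."""
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.plot(pair.modelled["temp_c"], pair.modelled["depth_m"], "-o", color="k",
            ms=3, label="modelled")
    ax.errorbar(
        pair.observed["temp_c"], pair.observed["depth_m"],
        xerr=pair.observed["temp_err_c"], yerr=pair.observed["depth_err_m"],
        fmt="s", ms=3, color="firebrick", lw=0.8, label="observed",
    )
    ax.invert_yaxis()
    ax.set_xlabel("temperature (degC)")
    ax.set_ylabel("depth (m)")
    ax.set_title(f"{pair.event.individual_id} {pair.event.start:%Y-%m-%d %H:%M}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
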