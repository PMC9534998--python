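"""Unstructured triangular mesh, sigma-layer geometry and hourly scalar fields.

The model grid follows the FVCOM convention: scalars (temperature, tidal
elevation) are resolved at mesh nodes for each terrain-following sigma layer.
Sigma levels run from 0 at the surface to -1 at the seabed, so layer depths
scale with the instantaneous water-column height (bathymetry + elevation) and
rise and fall with the tide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import xarray as xr

HOUR = pd.Timedelta(hours=1)

__all__ = [
    "Mesh",
    "SigmaScheme",
    "FieldSeries",
    "nearest_node",
    "nearest_nodes",
    "layer_depths",
    "bottom_temperature",
    "snap_hour",
    "load_fields",
    "save_fields",
]


class MeshError(ValueError):
    """Raised for structurally invalid meshes or unusable lookups."""


class FieldFormatError(ValueError):
    """Raised when a field file does not follow the expected NetCDF dialect."""


@dataclass
class Mesh:
    """Unstructured triangular mesh with per-node bathymetry.

    Parameters
    ----------
    node_ids
        Unique integer node identifiers. Stored sorted ascending; all other
        per-node arrays are reordered to match.
    x, y
        Planar projected coordinates in metres (e.g. a national grid). No
        geodesic arithmetic is performed.
    h
        Static bathymetry in metres below mean sea level (positive down).
    elements
        ``(n_elements, 3)`` array of node ids forming triangles.
    """

    node_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    h: np.ndarray
    elements: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64).reshape(-1, 3)
        n = self.node_ids.size
        if n == 0:
            raise MeshError("mesh has no nodes")
        if len({self.x.size, self.y.size, self.h.size}) != 1 or self.x.size != n:
            raise MeshError("per-node arrays have inconsistent lengths")
        if np.unique(self.node_ids).size != n:
            raise MeshError("node ids are not unique")
        order = np.argsort(self.node_ids)
        self.node_ids = self.node_ids[order]
        self.x = self.x[order]
        self.y = self.y[order]
        self.h = self.h[order]
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise MeshError("non-finite node coordinates")
        if np.any(self.h <= 0):
            raise MeshError("bathymetry must be positive (metres below MSL)")
        known = set(self.node_ids.tolist())
        for tri in self.elements:
            if len(set(tri.tolist())) != 3:
                raise MeshError(f"degenerate element {tri.tolist()}")
            for nid in tri:
                if int(nid) not in known:
                    raise MeshError(f"element references unknown node {int(nid)}")

    @property
    def n_nodes(self) -> int:
        return self.node_ids.size

    def index_of(self, node_id: int | np.ndarray) -> np.ndarray:
        """Positional index (row) of one or more node ids."""
        idx = np.searchsorted(self.node_ids, node_id)
        idx = np.clip(idx, 0, self.n_nodes - 1)
        if np.any(self.node_ids[idx] != node_id):
            raise MeshError(f"unknown node id(s) in {np.atleast_1d(node_id)}")
        return idx

    @cached_property
    def adjacency(self) -> dict[int, set[int]]:
        """Per-node neighbour sets derived from shared element membership."""
        adj: dict[int, set[int]] = {int(i): set() for i in self.node_ids}
        for a, b, c in self.elements:
            a, b, c = int(a), int(b), int(c)
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return adj


@dataclass(frozen=True)
class SigmaScheme:
    """Terrain-following vertical discretisation.

    ``sigma_levels`` holds L+1 levels from 0 (surface) to -1 (seabed),
    strictly decreasing; the L layer centres sit halfway between consecutive
    levels.  Layer 1 is nearest the surface and layer L hugs the seabed.
    """

    sigma_levels: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.sigma_levels, dtype=float)
        object.__setattr__(self, "sigma_levels", levels)
        if levels.ndim != 1 or levels.size < 2:
            raise ValueError("need at least two sigma levels")
        if levels[0] != 0.0 or levels[-1] != -1.0:
            raise ValueError("sigma levels must run from 0 to -1")
        if np.any(np.diff(levels) >= 0):
            raise ValueError("sigma levels must be strictly decreasing")

    @classmethod
    def uniform(cls, n_layers: int = 10) -> "SigmaScheme":
        return cls(np.linspace(0.0, -1.0, n_layers + 1))

    @property
    def n_layers(self) -> int:
        return self.sigma_levels.size - 1

    @property
    def layer_centres(self) -> np.ndarray:
        return 0.5 * (self.sigma_levels[:-1] + self.sigma_levels[1:])


@dataclass
class FieldSeries:
    """Hourly temperature and tidal-elevation fields on a mesh.

    ``temp`` is indexed ``(time, node, layer)`` in degC; ``zeta`` is tidal
    elevation in metres, positive up relative to mean sea level, indexed
    ``(time, node)``.  Node order matches ``Mesh.node_ids``.
    """

    hours: pd.DatetimeIndex
    temp: np.ndarray
    zeta: np.ndarray

    def __post_init__(self) -> None:
        self.hours = pd.DatetimeIndex(self.hours)
        self.temp = np.asarray(self.temp, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.temp.ndim != 3 or self.zeta.ndim != 2:
            raise ValueError("temp must be (time, node, layer); zeta (time, node)")
        if self.temp.shape[:2] != self.zeta.shape or self.temp.shape[0] != len(self.hours):
            raise ValueError("field array shapes inconsistent")
        steps = np.diff(self.hours.view("int64"))
        if len(self.hours) > 1 and (np.any(steps <= 0) or np.any(steps != steps[0])):
            raise ValueError("hours must be strictly increasing and evenly spaced")
        if np.any(~np.isfinite(self.temp)):
            raise ValueError("non-finite temperatures")

    @property
    def n_layers(self) -> int:
        return self.temp.shape[2]

    def bottom(self) -> np.ndarray:
        """Seabed-layer temperature, indexed (time, node)."""
        return self.temp[:, :, -1]


# ---------------------------------------------------------------------------
# lookups


def nearest_nodes(points: np.ndarray, mesh: Mesh, chunk: int = 4096) -> np.ndarray:
    """Nearest node id for each planar point, ties broken by lowest id.

    Exhaustive (chunked) distance scan: meshes here are small, and argmin over
    ascending ids gives a deterministic lowest-id tie-break for free.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2 or np.any(~np.isfinite(pts)):
        raise ValueError("points must be finite (n, 2) planar coordinates")
    out = np.empty(pts.shape[0], dtype=np.int64)
    for lo in range(0, pts.shape[0], chunk):
        sl = pts[lo : lo + chunk]
        d2 = (sl[:, [0]] - mesh.x) ** 2 + (sl[:, [1]] - mesh.y) ** 2
        out[lo : lo + chunk] = mesh.node_ids[np.argmin(d2, axis=1)]
    return out


def nearest_node(point, mesh: Mesh) -> int:
    """Nearest node id to a single point (lowest id on exact ties)."""
    return int(nearest_nodes(np.asarray(point, dtype=float).reshape(1, 2), mesh)[0])


def layer_depths(scheme: SigmaScheme, h: float, zeta: float = 0.0) -> np.ndarray:
    """Depths (m below the instantaneous surface) of layer centres 1..L.

    depth_k = |sigma_centre_k| * (h + zeta).  Strictly increasing with k and
    bounded above by the instantaneous water-column height.
    """
    column = float(h) + float(zeta)
    if float(h) <= 0:
        raise ValueError("bathymetry h must be positive")
    if column <= 0:
        raise ValueError(f"dry node: h + zeta = {column:g} <= 0")
    return np.abs(scheme.layer_centres) * column


def snap_hour(hours: pd.DatetimeIndex, when, tolerance: pd.Timedelta = pd.Timedelta(minutes=30)) -> int:
    """Index of the grid hour nearest to `when`, within `tolerance`."""
    when = pd.Timestamp(when)
    pos = int(np.searchsorted(hours, when))
    best, best_gap = None, None
    for cand in (pos - 1, pos):
        if 0 <= cand < len(hours):
            gap = abs(hours[cand] - when)
            if best_gap is None or gap < best_gap:
                best, best_gap = cand, gap
    if best is None or best_gap > tolerance:
        raise ValueError(f"{when} outside field time coverage (tolerance {tolerance})")
    return best


def bottom_temperature(fields: FieldSeries, mesh: Mesh, node_id: int, when) -> float:
    """Modelled seabed-layer temperature at a node and the nearest grid hour."""
    t = snap_hour(fields.hours, when)
    n = int(mesh.index_of(np.int64(node_id)))
    return float(fields.temp[t, n, -1])


# ---------------------------------------------------------------------------
# NetCDF I/O (FVCOM-like dialect; scipy backend, classic NetCDF)

_REQUIRED_VARS = ("x", "y", "h", "nv", "siglev", "temp", "zeta")


def save_fields(path, mesh: Mesh, scheme: SigmaScheme, fields: FieldSeries) -> str:
    """Write mesh + sigma scheme + hourly fields to a classic NetCDF file.

    Connectivity (`nv`) is stored with 1-based node indices per the FVCOM
    convention; node ids themselves are stored in `node_ids`.
    """
    # elements as 1-based positional indices into the node dimension
    nv = mesh.index_of(mesh.elements.ravel()).reshape(-1, 3) + 1
    ds = xr.Dataset(
        {
            "x": ("node", mesh.x),
            "y": ("node", mesh.y),
            "h": ("node", mesh.h),
            "node_ids": ("node", mesh.node_ids),
            "nv": (("element", "three"), nv.astype(np.int32)),
            "siglev": ("level", scheme.sigma_levels),
            "temp": (("time", "node", "layer"), fields.temp),
            "zeta": (("time", "node"), fields.zeta),
        },
        coords={"time": fields.hours},
        attrs={"Conventions": "benthoval-fvcom-dialect"},
    )
    ds["temp"].attrs["units"] = "degC"
    ds["zeta"].attrs["units"] = "m"
    ds.to_netcdf(path, engine="scipy",
                 encoding={"time": {"units": "hours since 1970-01-01", "dtype": "float64"}})
    return str(path)


def load_fields(path) -> tuple[Mesh, SigmaScheme, FieldSeries]:
    """Load a file written by :func:`save_fields` (round-trip inverse)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        for name in _REQUIRED_VARS:
            if name not in ds:
                raise FieldFormatError(f"missing required variable '{name}'")
        node_ids = (
            ds["node_ids"].values.astype(np.int64)
            if "node_ids" in ds
            else np.arange(ds.sizes["node"], dtype=np.int64)
        )
        nv = ds["nv"].values.astype(np.int64) - 1
        if nv.min() < 0 or nv.max() >= node_ids.size:
            raise FieldFormatError("element table references unknown node")
        mesh = Mesh(
            node_ids=node_ids,
            x=ds["x"].values,
            y=ds["y"].values,
            h=ds["h"].values,
            elements=node_ids[nv],
        )
        scheme = SigmaScheme(ds["siglev"].values)
        fields = FieldSeries(
            hours=pd.DatetimeIndex(ds["time"].values),
            temp=ds["temp"].values,
            zeta=ds["zeta"].values,
        )
    return mesh, scheme, fields
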