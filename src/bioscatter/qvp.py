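"""Quasi-vertical profile (QVP) construction.

A QVP collapses one sector-masked constant-elevation PPI sweep into a
single pseudo-vertical profile: each range gate is averaged over the
contributing azimuths and the result is assigned to the height bin that
the beam centerline reaches at that slant range.  Concatenating the
per-scan profiles over a night yields a time x height grid per variable
— the substrate of the bioscatterer classification.

Averaging conventions follow standard QVP practice: the reflectivity
factors Z_H and Z_V are averaged in linear units (mm^6 m^-3) and
converted back to dBZ, while Z_DR, RHO_HV and K_DP are averaged
arithmetically in their native units.  RHO_HV estimates above 1
(tolerated up to 1.2 at ingest) are clipped to 1 here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from bioscatter.radar_io import VARIABLES, PolarScan

log = logging.getLogger(__name__)

#: Effective earth radius for the 4/3-earth beam propagation model, metres.
R_EFF_M = (4.0 / 3.0) * 6371.0e3

#: Variables averaged in linear reflectivity units (mm^6 m^-3).
LINEAR_VARS = ("ZH", "ZV")


def beam_height(slant_range_m, elevation_deg, model: str = "flat"):
    """Height of the beam centerline above the antenna.

    ``flat`` returns ``r * sin(theta)``; ``four_thirds_earth`` the
    standard effective-earth-radius form
    ``sqrt(r^2 + R'^2 + 2 r R' sin(theta)) - R'`` with
    ``R' = (4/3) * 6371 km``.  Both are strictly increasing in range and
    elevation, and the spherical model never falls below the flat one.
    For the 3-degree beam used throughout, the flat model gives 1.57 km
    at 30 km slant range — the radius of a 60-km-diameter QVP cone.
    """
    r = np.asarray(slant_range_m, dtype=float)
    if np.any(r < 0):
        raise ValueError("slant range must be non-negative")
    if not (0.0 < elevation_deg < 90.0):
        raise ValueError("elevation must lie in (0, 90) degrees")
    theta = np.deg2rad(elevation_deg)
    if model == "flat":
        h = r * np.sin(theta)
    elif model == "four_thirds_earth":
        h = np.sqrt(r**2 + R_EFF_M**2 + 2.0 * r * R_EFF_M * np.sin(theta)) - R_EFF_M
    else:
        raise ValueError(f"unknown beam model {model!r}")
    return h if h.ndim else float(h)


@dataclass
class QVPColumn:
    """One scan's azimuthally averaged profile on a height grid."""

    timestamp: object
    heights_m: np.ndarray
    values: dict  # variable -> masked (n_heights,) array
    counts: dict  # variable -> (n_heights,) int array of contributing azimuths

    def __post_init__(self):
        self.heights_m = np.asarray(self.heights_m, dtype=float)
        if np.any(np.diff(self.heights_m) <= 0):
            raise ValueError("height grid must be strictly increasing")


@dataclass
class QVPSeries:
    """Time x height grids of the five variables (plus counts)."""

    times: np.ndarray  # sorted datetime64[ns]
    heights_m: np.ndarray
    grids: dict  # variable -> masked (n_times, n_heights) array
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times)
        self.heights_m = np.asarray(self.heights_m, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= np.timedelta64(0, "ns")):
            raise ValueError("times must be strictly increasing")
        shape = (self.times.size, self.heights_m.size)
        for name, g in self.grids.items():
            if g.shape != shape:
                raise ValueError(f"grid {name} has shape {g.shape}, expected {shape}")

    @property
    def shape(self):
        return self.times.size, self.heights_m.size

    def to_xarray(self) -> xr.Dataset:
        data = {
            name: (("time", "height"), np.ma.filled(g.astype(float), np.nan))
            for name, g in self.grids.items()
        }
        for name, c in self.counts.items():
            data[f"count_{name}"] = (("time", "height"), np.asarray(c))
        return xr.Dataset(
            data, coords={"time": self.times, "height": self.heights_m}
        )

    def to_netcdf(self, path) -> str:
        self.to_xarray().to_netcdf(path, engine="scipy")
        return str(path)

    @classmethod
    def from_netcdf(cls, path) -> "QVPSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            grids, counts = {}, {}
            for name in ds.data_vars:
                if name.startswith("count_"):
                    counts[name[len("count_"):]] = ds[name].values.astype(int)
                else:
                    grids[name] = np.ma.masked_invalid(ds[name].values.astype(float))
            return cls(
                times=ds["time"].values,
                heights_m=ds["height"].values.astype(float),
                grids=grids,
                counts=counts,
            )


@dataclass(frozen=True)
class NightWindow:
    """A half-open UTC interval [start, end) labelling one trap night."""

    night_id: str
    start: object
    end: object

    def __post_init__(self):
        if not np.datetime64(self.start) < np.datetime64(self.end):
            raise ValueError(f"night {self.night_id}: start must precede end")


def _to_linear(dbz):
    return np.ma.power(10.0, dbz / 10.0)


def _to_dbz(linear):
    return 10.0 * np.ma.log10(linear)


def build_qvp(
    scan: PolarScan,
    height_grid_m: np.ndarray,
    min_count: int = 30,
    beam_model: str = "flat",
    statistic: str = "mean",
) -> QVPColumn:
    """Azimuthally average one sector-masked scan onto a height grid.

    ``height_grid_m`` gives bin edges (strictly increasing).  For each
    range gate the unmasked azimuths are averaged per variable (Z_H and
    Z_V in linear units, the rest arithmetically); the gate's value
    lands in the bin containing its beam height, and gates sharing a bin
    are combined with contribution-count weights.  Bins receiving fewer
    than ``min_count`` azimuth samples (at any contributing gate summed)
    are masked.  ``statistic='median'`` replaces the azimuthal mean with
    a median for robustness experiments.
    """
    edges = np.asarray(height_grid_m, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("height grid must contain at least two increasing edges")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")

    n_bins = edges.size - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    heights = beam_height(scan.ranges_m, scan.elevation_deg, beam_model)
    bin_idx = np.searchsorted(edges, heights, side="right") - 1
    in_grid = (bin_idx >= 0) & (bin_idx < n_bins) & (heights < edges[-1])

    values, counts = {}, {}
    any_unmasked = False
    for name in scan.fields:
        arr = scan.fields[name]
        if name == "RHOHV":
            arr = np.ma.clip(arr, None, 1.0)
        work = _to_linear(arr) if name in LINEAR_VARS else arr
        if statistic == "mean":
            gate_val = np.ma.mean(work, axis=0)
        else:
            gate_val = np.ma.median(work, axis=0)
        gate_n = (~np.ma.getmaskarray(work)).sum(axis=0)
        any_unmasked |= bool(gate_n.sum())

        bin_val = np.ma.masked_all(n_bins)
        bin_n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = in_grid & (bin_idx == b) & (gate_n > 0)
            if not sel.any():
                continue
            w = gate_n[sel].astype(float)
            bin_n[b] = int(w.sum())
            if statistic == "mean":
                bin_val[b] = np.ma.average(gate_val[sel], weights=w)
            else:
                bin_val[b] = np.ma.median(gate_val[sel])
        bin_val = np.ma.masked_where(bin_n < min_count, bin_val)
        if name in LINEAR_VARS:
            bin_val = _to_dbz(bin_val)
        values[name] = bin_val
        counts[name] = bin_n
    if not any_unmasked:
        warnings.warn("all azimuths masked; QVP column is fully masked")
    return QVPColumn(
        timestamp=scan.timestamp, heights_m=centers, values=values, counts=counts
    )


def concatenate(columns) -> QVPSeries:
    """Stack per-scan columns into a time-sorted series on a shared grid."""
    columns = list(columns)
    if not columns:
        raise ValueError("no columns to concatenate")
    grid = columns[0].heights_m
    for c in columns[1:]:
        if c.heights_m.shape != grid.shape or not np.allclose(c.heights_m, grid):
            raise ValueError("columns do not share a height grid")
    times = np.array([np.datetime64(c.timestamp.replace(tzinfo=None)
                                    if getattr(c.timestamp, "tzinfo", None)
                                    else c.timestamp, "ns")
                      for c in columns])
    order = np.argsort(times)
    if np.unique(times).size != times.size:
        raise ValueError("duplicate timestamps in QVP columns")
    names = list(columns[0].values)
    grids = {
        name: np.ma.vstack([columns[i].values[name] for i in order]) for name in names
    }
    counts = {
        name: np.vstack([columns[i].counts[name] for i in order]) for name in names
    }
    return QVPSeries(times=times[order], heights_m=grid, grids=grids, counts=counts)


def window_nights(series: QVPSeries, windows) -> dict:
    """Split a series into per-night sub-series on half-open UTC windows.

    Windows must not overlap.  A window containing no scans yields an
    empty series (with a warning) rather than being dropped, so nightly
    bookkeeping stays aligned with the trap schedule.
    """
    windows = list(windows)
    spans = sorted(
        ((np.datetime64(w.start), np.datetime64(w.end), w.night_id) for w in windows)
    )
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"night windows {n1!r} and {n2!r} overlap")
    out = {}
    for w in windows:
        lo, hi = np.datetime64(w.start), np.datetime64(w.end)
        sel = (series.times >= lo) & (series.times < hi)
        if not sel.any():
            warnings.warn(f"night {w.night_id!r} contains no scans")
        out[w.night_id] = QVPSeries(
            times=series.times[sel],
            heights_m=series.heights_m,
            grids={k: g[sel] for k, g in series.grids.items()},
            counts={k: c[sel] for k, c in series.counts.items()},
        )
    return out


def default_height_grid(top_m: float = 2000.0, width_m: float = 25.0) -> np.ndarray:
    """Bin edges 0..top in fixed-width steps (default 25 m to 2 km)."""
    return np.arange(0.0, top_m + width_m / 2, width_m)
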