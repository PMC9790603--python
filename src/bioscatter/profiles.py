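"""Cluster characterization: box-plot summaries, occupancy, abundance.

After the divisive clustering has labelled the QVP cells, this module
summarizes each cluster in native units (the five radar variables plus
cell altitude), flags the meteorological (rain) cluster by its
polarimetric signature, and counts nightly bioscatterer cells — the
radar-side abundance series that is compared with light-trap catches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bioscatter.bca import UNCLASSIFIED, FeatureTable, Labeling
from bioscatter.radar_io import VARIABLES


@dataclass
class VariableSummary:
    """Tukey box-plot statistics for one cluster and one variable."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_outliers: int
    n: int

    def __post_init__(self):
        assert self.q1 <= self.median <= self.q3


@dataclass
class ClusterProfile:
    """Per-cluster, per-variable summaries plus per-cluster means."""

    summaries: dict  # cluster id -> {variable -> VariableSummary}
    means: pd.DataFrame  # index: cluster id, columns: variables (+ ALTITUDE)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid, by_var in self.summaries.items():
            for var, s in by_var.items():
                for stat in ("q1", "median", "q3", "whisker_low", "whisker_high",
                             "n_outliers", "n"):
                    rows.append(
                        {"cluster": cid, "variable": var, "statistic": stat,
                         "value": getattr(s, stat)}
                    )
        return pd.DataFrame(rows)


def _tukey_summary(values: np.ndarray) -> VariableSummary:
    """Quartiles by linear interpolation; whiskers at the most extreme
    points within 1.5 IQR of the box; everything beyond is an outlier."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return VariableSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        n_outliers=int(((v < lo_fence) | (v > hi_fence)).sum()),
        n=v.size,
    )


def cluster_summary(labeling: Labeling, features: FeatureTable) -> ClusterProfile:
    """Box-plot summaries of every cluster in native units.

    Uses the unstandardized feature values; altitude is summarized from
    the per-cell heights carried by the feature table.
    """
    summaries, mean_rows = {}, {}
    cols = list(VARIABLES) + (["ALTITUDE"] if features.heights_m is not None else [])
    for cid in labeling.leaf_ids:
        mem = labeling.members(cid)
        if mem.size == 0:
            raise ValueError(f"cluster {cid} has no members")
        by_var = {}
        means = {}
        for j, var in enumerate(VARIABLES):
            vals = features.raw[mem, j]
            by_var[var] = _tukey_summary(vals)
            means[var] = float(vals.mean())
        if features.heights_m is not None:
            alts = features.heights_m[mem]
            by_var["ALTITUDE"] = _tukey_summary(alts)
            means["ALTITUDE"] = float(np.mean(alts))
        summaries[cid] = by_var
        mean_rows[cid] = means
    means = pd.DataFrame.from_dict(mean_rows, orient="index")[cols]
    return ClusterProfile(summaries=summaries, means=means)


def identify_rain(
    profile: ClusterProfile,
    rho_threshold: float = 0.95,
    zdr_threshold_db: float = 0.5,
):
    """Pick the meteorological cluster, if any.

    The candidate is the cluster with the highest mean RHO_HV; it is
    flagged meteorological when that mean exceeds ``rho_threshold`` and
    its mean Z_DR is within ``zdr_threshold_db`` of 0 dB — the light-rain
    signature (near-spherical, highly correlated scatterers).  Returns
    the cluster id, or ``None`` when no cluster is meteorological.
    """
    if profile.means.empty:
        raise ValueError("profile has no clusters")
    candidate = profile.means["RHOHV"].idxmax()
    row = profile.means.loc[candidate]
    if row["RHOHV"] > rho_threshold and abs(row["ZDR"]) < zdr_threshold_db:
        return candidate
    return None


def occupancy(label_grid: np.ndarray, heights_m: np.ndarray, times: np.ndarray):
    """Per-time, per-cluster cell counts and occupied height extremes.

    Returns a tidy DataFrame (time, cluster, n_cells, height_min,
    height_max); clusters absent at a time get count 0 and NaN heights.
    """
    grid = np.asarray(label_grid)
    clusters = np.unique(grid[grid != UNCLASSIFIED])
    rows = []
    for ti, t in enumerate(times):
        for cid in clusters:
            sel = grid[ti] == cid
            n = int(sel.sum())
            rows.append(
                {
                    "time": t,
                    "cluster": int(cid),
                    "n_cells": n,
                    "height_min": float(heights_m[sel].min()) if n else np.nan,
                    "height_max": float(heights_m[sel].max()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AbundanceSeries:
    """Nightly per-cluster cell counts and bioscatterer totals."""

    per_cluster: pd.DataFrame  # index: night_id, columns: cluster ids
    total: pd.Series  # night_id -> summed bioscatterer cells
    bio_ids: tuple


def nightly_abundance(label_grids: dict, bio_ids) -> AbundanceSeries:
    """Count labelled cells per night and sum over bioscatterer clusters.

    ``label_grids`` maps night_id -> label grid; ``bio_ids`` designates
    the bioscatterer clusters (the rain cluster and the sentinel are
    excluded from the total).
    """
    bio_ids = tuple(bio_ids)
    all_ids = set()
    for grid in label_grids.values():
        g = np.asarray(grid)
        all_ids.update(int(v) for v in np.unique(g[g != UNCLASSIFIED]))
    unknown = set(bio_ids) - all_ids
    if unknown and all_ids:
        raise ValueError(f"unknown bioscatterer cluster id(s): {sorted(unknown)}")
    cols = sorted(all_ids | set(bio_ids))
    counts = {}
    for night, grid in label_grids.items():
        g = np.asarray(grid)
        counts[night] = {c: int((g == c).sum()) for c in cols}
    per_cluster = pd.DataFrame.from_dict(counts, orient="index")
    if per_cluster.empty:
        per_cluster = pd.DataFrame(columns=cols)
    total = per_cluster[list(bio_ids)].sum(axis=1) if bio_ids else pd.Series(dtype=int)
    return AbundanceSeries(per_cluster=per_cluster, total=total, bio_ids=bio_ids)
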