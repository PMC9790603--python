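"""Synthetic radar nights and coupled moth catches.

The generator emulates the statistical structure the pipeline assumes:
a season of nightly QVP grids populated by a small number of scatterer
populations — four bioscatterer classes plus light rain — each a
truncated multivariate normal in the five-variable space with its own
altitude envelope and activity window, plus a pair of light-trap catch
series stochastically coupled to the nightly bioscatterer cell counts.

The ``fig4`` preset encodes the published polarimetric signatures: rain
with RHO_HV near 0.97 and reflectivities near 18/19 dBZ; bioscatterer
classes with reflectivities between 0 and -12 dBZ, Z_DR between 0 and
2 dB, RHO_HV below 0.7 and negative K_DP (most negative about
-2.5 deg/km).  Within-population spreads are kept well below the
between-population separations so the preset is separable; a ``hard``
variant doubles them for stress testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from bioscatter.bca import UNCLASSIFIED
from bioscatter.qvp import QVPSeries
from bioscatter.radar_io import VARIABLES


@dataclass(frozen=True)
class PopulationSpec:
    """One scatterer population: polarimetric law + space-time envelope."""

    name: str
    mean: tuple  # (ZH dBZ, ZV dBZ, ZDR dB, RHOHV, KDP deg/km)
    sd: tuple  # diagonal standard deviations, same order
    height_range_m: tuple  # (min, max) altitude envelope
    time_window: tuple  # (start, end) fractions of the night, half-open
    occupancy: float = 1.0  # fill probability inside the envelope
    nights: str = "all"  # 'all' or 'every_k' with int k via night_step
    night_step: int = 1  # population active on nights where idx % step == 0

    def covariance(self) -> np.ndarray:
        return np.diag(np.asarray(self.sd, dtype=float) ** 2)

    def active(self, night_idx: int) -> bool:
        if self.nights == "all":
            return True
        return night_idx % self.night_step == 0


@dataclass(frozen=True)
class ScenePreset:
    """A full generative scene specification.

    Populations listed later take priority where envelopes overlap.
    """

    populations: tuple
    n_nights: int = 33
    times_per_night: int = 16
    height_edges_m: tuple = tuple(np.arange(0.0, 1001.0, 25.0))
    seed: int = 0
    night_occupancy_sd: float = 0.4  # lognormal sigma of nightly activity
    first_night: int = 0  # global index of the first generated night

    def __post_init__(self):
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")


def preset_fig4(seed: int = 0, hard: bool = False) -> ScenePreset:
    """Five-population preset mirroring the published cluster signatures.

    Population means (ZH, ZV, ZDR, RHOHV, KDP):

    * ``bio1`` (-10, -12, 1.0, 0.68, -0.5): sparse small elongated
      scatterers, present through the column all night.
    * ``bio2`` (0, -1, 1.0, 0.695, -1.0): denser, larger scatterers
      dominating near the surface mid-night.
    * ``bio3`` (-5, -7, 2.0, 0.60, -0.8): very elongated, decorrelated
      scatterers between 300 and 500 m.
    * ``bio4`` (-4, -4, 0.0, 0.65, -2.5): more spherical scatterers
      below 300 m later in the night.
    * ``rain`` (18, 19, 0.0, 0.97, 0.3): light rain as transient
      full-column interludes on a third of the nights.

    Diagonal SDs default to (2, 2, 0.3, 0.02, 0.3); ``hard=True``
    doubles them.
    """
    sd = (2.0, 2.0, 0.3, 0.02, 0.3)
    if hard:
        sd = tuple(2 * s for s in sd)
    pops = (
        PopulationSpec(
            name="bio1", mean=(-10.0, -12.0, 1.0, 0.68, -0.5), sd=sd,
            height_range_m=(100.0, 800.0), time_window=(0.0, 1.0), occupancy=0.5,
        ),
        PopulationSpec(
            name="bio2", mean=(0.0, -1.0, 1.0, 0.695, -1.0), sd=sd,
            height_range_m=(0.0, 300.0), time_window=(0.25, 0.75), occupancy=0.8,
        ),
        PopulationSpec(
            name="bio3", mean=(-5.0, -7.0, 2.0, 0.60, -0.8), sd=sd,
            height_range_m=(300.0, 500.0), time_window=(0.30, 0.80), occupancy=0.8,
        ),
        PopulationSpec(
            name="bio4", mean=(-4.0, -4.0, 0.0, 0.65, -2.5), sd=sd,
            height_range_m=(0.0, 300.0), time_window=(0.60, 1.0), occupancy=0.7,
        ),
        PopulationSpec(
            name="rain", mean=(18.0, 19.0, 0.0, 0.97, 0.3), sd=sd,
            height_range_m=(0.0, 1000.0), time_window=(0.35, 0.65), occupancy=1.0,
            nights="every_k", night_step=3,
        ),
    )
    return ScenePreset(populations=pops, seed=seed)


def preset_single(seed: int = 0) -> ScenePreset:
    """A one-population control scene (no meteorological component)."""
    pops = (
        PopulationSpec(
            name="bio1", mean=(-10.0, -12.0, 1.0, 0.68, -0.5),
            sd=(2.0, 2.0, 0.3, 0.02, 0.3),
            height_range_m=(0.0, 1000.0), time_window=(0.0, 1.0), occupancy=0.8,
        ),
    )
    return ScenePreset(populations=pops, seed=seed)


PRESETS = {"fig4": preset_fig4, "fig4_hard": lambda seed=0: preset_fig4(seed, hard=True),
           "single": preset_single}


@dataclass
class SceneTruth:
    """Ground-truth assignment of every cell of a generated scene."""

    label_grid: np.ndarray  # (n_times_total, n_heights) population index or -1
    population_names: tuple
    night_of_time: np.ndarray  # (n_times_total,) night index per scan time
    truncation_resamples: int = 0

    def night_bio_cells(self, bio_names=None) -> pd.Series:
        """Nightly cell counts summed over bioscatterer populations."""
        names = self.population_names
        if bio_names is None:
            bio_names = [n for n in names if n != "rain"]
        bio_idx = [names.index(n) for n in bio_names]
        nights = np.unique(self.night_of_time)
        counts = {}
        for night in nights:
            sub = self.label_grid[self.night_of_time == night]
            counts[f"night{night:03d}"] = int(np.isin(sub, bio_idx).sum())
        return pd.Series(counts)


def _sample_population(pop: PopulationSpec, n: int, rng) -> tuple:
    """Draw n cells; RHO_HV draws outside (0, 1] are rejected and redrawn."""
    mean = np.asarray(pop.mean, dtype=float)
    cov = pop.covariance()
    x = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    rho_col = VARIABLES.index("RHOHV")
    resamples = 0
    for _ in range(1000):
        bad = (x[:, rho_col] <= 0) | (x[:, rho_col] > 1.0)
        if not bad.any():
            break
        resamples += int(bad.sum())
        x[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()),
                                         method="cholesky")
    else:
        raise RuntimeError(f"RHO_HV truncation failed to converge for {pop.name}")
    return x, resamples


def _night_seed(seed: int, night_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, night_idx]))


def make_scene(preset: ScenePreset, seed: int | None = None):
    """Generate a full-season QVP series plus ground truth.

    Each night is generated independently from a seed derived from
    ``(seed, night index)``, so generating a season equals concatenating
    single-night generations.  Cells covered by no active population are
    masked; overlaps resolve to the later-listed population.  Returns
    ``(QVPSeries, SceneTruth)``.
    """
    seed = preset.seed if seed is None else seed
    edges = np.asarray(preset.height_edges_m, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nh = centers.size
    nt = preset.times_per_night
    n_total = preset.n_nights * nt

    grids = {
        v: np.ma.masked_all((n_total, nh)) for v in VARIABLES
    }
    label = np.full((n_total, nh), UNCLASSIFIED, dtype=int)
    night_of_time = np.repeat(
        preset.first_night + np.arange(preset.n_nights), nt
    )
    resamples = 0

    t_frac = (np.arange(nt) + 0.5) / nt
    for local in range(preset.n_nights):
        night = preset.first_night + local
        rng = _night_seed(seed, night)
        base = local * nt
        # nightly activity factor per population (lognormal, capped at 1)
        for pidx, pop in enumerate(preset.populations):
            factor = float(np.exp(rng.normal(0.0, preset.night_occupancy_sd)))
            if not pop.active(night):
                continue
            p_fill = min(1.0, pop.occupancy * factor)
            t_in = (t_frac >= pop.time_window[0]) & (t_frac < pop.time_window[1])
            h_in = (centers >= pop.height_range_m[0]) & (
                centers < pop.height_range_m[1]
            )
            cell_mask = np.outer(t_in, h_in)
            fill = rng.random(cell_mask.shape) < p_fill
            chosen = cell_mask & fill
            n_cells = int(chosen.sum())
            if n_cells == 0:
                continue
            draws, res = _sample_population(pop, n_cells, rng)
            resamples += res
            rows, cols = np.nonzero(chosen)
            label[base + rows, cols] = pidx
            for j, v in enumerate(VARIABLES):
                grids[v][base + rows, cols] = draws[:, j]

    # one scan every 15 minutes, nights spaced a day apart
    t0 = np.datetime64("2017-06-01T21:00:00", "ns")
    times = (
        t0
        + np.repeat(preset.first_night + np.arange(preset.n_nights), nt)
        * np.timedelta64(1, "D")
        + np.tile(np.arange(nt), preset.n_nights) * np.timedelta64(15, "m")
    )
    counts = {
        v: (~np.ma.getmaskarray(grids[v])).astype(int) for v in VARIABLES
    }
    series = QVPSeries(times=times, heights_m=centers, grids=grids, counts=counts)
    truth = SceneTruth(
        label_grid=label,
        population_names=tuple(p.name for p in preset.populations),
        night_of_time=night_of_time,
        truncation_resamples=resamples,
    )
    return series, truth


# -- coupled light-trap catches -------------------------------------------

@dataclass(frozen=True)
class CatchCoupling:
    """Log-log coupling of nightly catch totals to bioscatterer cells.

    Expected total catch on night i is
    ``exp(alpha + beta * log(1 + cells_i))`` times lognormal noise with
    sigma ``noise_sd``.  ``beta = 0`` decouples the catches entirely.
    The defaults give nightly totals of about 60 moths and a Spearman
    correlation with the radar cell counts of about 0.55-0.6, the
    strength of coupling the analysis is designed to detect.
    """

    alpha: float = -1.5
    beta: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("coupling slope beta must be non-negative")


def species_pool(n_species: int = 40, seed: int = 12345) -> pd.DataFrame:
    """A plausible macro-moth trait pool (measured traits, mm).

    Species sizes span roughly an order of magnitude in body length;
    correlated widths/lengths keep the morphometrics internally
    consistent.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    body = rng.lognormal(np.log(15.0), 0.35, n_species)  # 6..40 mm
    fore = body * rng.normal(0.95, 0.08, n_species)
    thorax_l = body * rng.normal(0.28, 0.03, n_species)
    abdo_l = body * rng.normal(0.62, 0.05, n_species)
    thorax_w = body * rng.normal(0.18, 0.02, n_species)
    abdo_w = body * rng.normal(0.14, 0.02, n_species)
    # dorsoventrally flattened thorax: depth a species-specific fraction
    # of width, so the anterior aspect ratio varies across the pool
    thorax_d = thorax_w * rng.uniform(0.7, 1.0, n_species)
    df = pd.DataFrame(
        {
            "forewing_length": fore,
            "body_length": body,
            "thorax_length": thorax_l,
            "abdomen_length": abdo_l,
            "thorax_width": thorax_w,
            "abdomen_width": abdo_w,
            "thorax_depth": thorax_d,
        },
        index=[f"species_{i:03d}" for i in range(n_species)],
    ).clip(lower=0.5)
    return df


def _log_series_profile(n_species: int, theta: float = 0.95) -> np.ndarray:
    """Fixed relative-abundance profile p_k ~ theta^k / k (log-series)."""
    k = np.arange(1, n_species + 1)
    p = theta**k / k
    return p / p.sum()


def make_catches(
    night_bio_cells: pd.Series,
    species: pd.DataFrame,
    coupling: CatchCoupling = CatchCoupling(),
    seed: int = 0,
    site2_nights: int = 16,
):
    """Generate two light-trap catch tables coupled to the radar scene.

    Site 1 operates every night; site 2 on ``site2_nights`` of them
    (evenly spread).  Per night and site, the total catch is drawn
    around the coupling's expectation and allocated to species by a
    fixed log-series relative-abundance profile.  Returns
    ``{"site1": DataFrame, "site2": DataFrame}`` of night x species
    counts (site 2 restricted to its active nights).
    """
    if species.empty:
        raise ValueError("species pool is empty")
    rng = np.random.default_rng(seed)
    nights = list(night_bio_cells.index)
    n_nights = len(nights)
    profile = _log_series_profile(len(species))
    site2_active = set(
        np.linspace(0, n_nights - 1, min(site2_nights, n_nights)).round().astype(int)
    )
    tables = {"site1": {}, "site2": {}}
    for i, night in enumerate(nights):
        cells = float(night_bio_cells.iloc[i])
        lam = np.exp(coupling.alpha + coupling.beta * np.log1p(cells))
        for site in ("site1", "site2"):
            if site == "site2" and i not in site2_active:
                continue
            noise = np.exp(rng.normal(0.0, coupling.noise_sd))
            total = int(np.round(lam * noise))
            counts = rng.multinomial(total, profile) if total > 0 else np.zeros(
                len(species), dtype=int
            )
            tables[site][night] = counts
    out = {}
    for site, rows in tables.items():
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
        df.columns = list(species.index)
        out[site] = df
    return out
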