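"""Reading, writing, calibrating and sector-masking constant-elevation scans.

A :class:`PolarScan` holds one plan-position-indicator (PPI) sweep: a
rays x gates grid of the five polarimetric variables the classification
uses — horizontal and vertical reflectivity factor Z_H, Z_V [dBZ],
differential reflectivity Z_DR [dB], co-polar correlation coefficient
RHO_HV [-] and specific differential phase K_DP [deg/km] — together with
the beam geometry.  Missing gates are carried as a mask, never as
sentinel values.

Three on-disk dialects are supported: a self-describing NetCDF fixture
dialect (the package's own, round-trip exact), CfRadial-style NetCDF and
ODIM_H5-style HDF5 with the common field aliases (DBZH, DBZV, ZDR,
RHOHV, KDP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone

import h5py
import numpy as np
import xarray as xr

log = logging.getLogger(__name__)

#: Canonical variable order for every five-column matrix in the package.
VARIABLES = ("ZH", "ZV", "ZDR", "RHOHV", "KDP")

#: ODIM / CfRadial field aliases mapped onto canonical names.
FIELD_ALIASES = {
    "DBZH": "ZH",
    "DBZV": "ZV",
    "ZDR": "ZDR",
    "RHOHV": "RHOHV",
    "KDP": "KDP",
}

_FILL = -9999.0


class RadarIOError(ValueError):
    """Raised for malformed or incomplete scan files."""


@dataclass
class PolarScan:
    """One constant-elevation sweep with the five polarimetric fields.

    Parameters
    ----------
    timestamp : datetime
        Scan time (UTC).
    elevation_deg : float
        Antenna elevation angle, degrees above the horizon, in (0, 90).
    azimuths_deg : ndarray, shape (n_rays,)
        Beam azimuths, degrees clockwise from North, in [0, 360),
        strictly increasing.
    ranges_m : ndarray, shape (n_gates,)
        Gate-center slant ranges in metres, strictly increasing, > 0.
    fields : dict of str -> masked array, shape (n_rays, n_gates)
        The five variables keyed by canonical name.
    """

    timestamp: datetime
    elevation_deg: float
    azimuths_deg: np.ndarray
    ranges_m: np.ndarray
    fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.azimuths_deg = np.asarray(self.azimuths_deg, dtype=float)
        self.ranges_m = np.asarray(self.ranges_m, dtype=float)
        self.fields = {k: np.ma.masked_invalid(v) for k, v in self.fields.items()}
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        if not self.fields:
            raise RadarIOError("scan has no fields")
        if not (0.0 < self.elevation_deg < 90.0):
            raise RadarIOError(f"elevation {self.elevation_deg} outside (0, 90)")
        az = self.azimuths_deg
        if az.ndim != 1 or np.any(az < 0) or np.any(az >= 360):
            raise RadarIOError("azimuths must be 1-D and within [0, 360)")
        if np.any(np.diff(az) <= 0):
            raise RadarIOError("azimuths must be strictly increasing")
        r = self.ranges_m
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise RadarIOError("ranges must be positive and strictly increasing")
        shape = (az.size, r.size)
        for name, arr in self.fields.items():
            if arr.shape != shape:
                raise RadarIOError(
                    f"field {name} has shape {arr.shape}, expected {shape}"
                )
        if "RHOHV" in self.fields:
            rho = self.fields["RHOHV"]
            bad = (rho <= 0) | (rho > 1.2)
            if bad.any():
                raise RadarIOError("RHO_HV values outside (0, 1.2] present")
            if (rho > 1.0).any():
                log.warning(
                    "RHO_HV contains %d noisy estimates > 1 (tolerated up to 1.2)",
                    int((rho > 1.0).sum()),
                )

    @property
    def shape(self):
        return self.azimuths_deg.size, self.ranges_m.size

    def copy(self) -> "PolarScan":
        return PolarScan(
            timestamp=self.timestamp,
            elevation_deg=self.elevation_deg,
            azimuths_deg=self.azimuths_deg.copy(),
            ranges_m=self.ranges_m.copy(),
            fields={k: v.copy() for k, v in self.fields.items()},
        )


@dataclass(frozen=True)
class CalibrationOffsets:
    """Additive calibration constants, dB.

    Z_V is not offset independently: after calibration it is recomputed
    as Z_H - Z_DR so the three reflectivity quantities stay consistent.
    """

    zh_offset_db: float = 0.0
    zdr_offset_db: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.zh_offset_db) and np.isfinite(self.zdr_offset_db)):
            raise ValueError("calibration offsets must be finite")


@dataclass(frozen=True)
class SectorMask:
    """Azimuth intervals to blank out (blocked or switched-off sectors).

    Each interval is ``[start_deg, end_deg]`` clockwise from North with
    inclusive endpoints; intervals may wrap through 0 (start > end).
    """

    intervals: tuple = ()

    def __post_init__(self):
        ivs = []
        for start, end in self.intervals:
            if not (0 <= start < 360 and 0 <= end < 360):
                raise ValueError(f"sector endpoints must lie in [0, 360): {(start, end)}")
            ivs.append((float(start), float(end)))
        object.__setattr__(self, "intervals", tuple(ivs))

    def contains(self, azimuths_deg: np.ndarray) -> np.ndarray:
        """Boolean membership of each azimuth in any interval (inclusive)."""
        az = np.asarray(azimuths_deg, dtype=float) % 360.0
        hit = np.zeros(az.shape, dtype=bool)
        for start, end in self.intervals:
            if start <= end:
                hit |= (az >= start) & (az <= end)
            else:  # wraps through North
                hit |= (az >= start) | (az <= end)
        return hit


# -- file I/O -------------------------------------------------------------

def read_scan(path, dialect: str = "fixture") -> PolarScan:
    """Read a constant-elevation scan.

    ``dialect`` is one of ``fixture`` (the package's NetCDF dialect),
    ``cfradial`` or ``odim``.  All five canonical fields must be present
    (under their aliases for the standard dialects); a missing field is
    an error naming every absent alias.
    """
    if dialect == "fixture":
        return _read_fixture(path)
    if dialect == "cfradial":
        return _read_cfradial(path)
    if dialect == "odim":
        return _read_odim(path)
    raise RadarIOError(f"unknown dialect {dialect!r}; expected fixture|cfradial|odim")


def write_scan(scan: PolarScan, path) -> str:
    """Write a scan in the fixture NetCDF dialect (bit-exact round trip)."""
    scan.validate()
    data_vars = {}
    for name in scan.fields:
        arr = scan.fields[name]
        data_vars[name] = (
            ("ray", "gate"),
            np.ma.filled(arr.astype(np.float64), _FILL),
            {"_FillValue": _FILL},
        )
    ds = xr.Dataset(
        data_vars,
        coords={
            "azimuth": ("ray", scan.azimuths_deg.astype(np.float64)),
            "range": ("gate", scan.ranges_m.astype(np.float64)),
        },
        attrs={
            "Conventions": "bioscatter-fixture-1",
            "elevation_deg": float(scan.elevation_deg),
            "timestamp": scan.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
        },
    )
    ds.to_netcdf(path, engine="scipy")
    return str(path)


def _require_fields(present, required=VARIABLES, alias_map=None):
    missing = [f for f in required if f not in present]
    if missing:
        if alias_map:
            rev = {v: k for k, v in alias_map.items()}
            missing = [rev.get(m, m) for m in missing]
        raise RadarIOError(f"required field(s) absent: {', '.join(missing)}")


def _read_fixture(path) -> PolarScan:
    with xr.open_dataset(path, mask_and_scale=False, engine="scipy") as ds:
        present = set(ds.data_vars)
        _require_fields(present)
        fields = {}
        for name in VARIABLES:
            raw = ds[name].values.astype(np.float64)
            fill = ds[name].attrs.get("_FillValue", _FILL)
            fields[name] = np.ma.masked_equal(raw, fill)
        ts = datetime.strptime(ds.attrs["timestamp"], "%Y-%m-%dT%H:%M:%SZ").replace(
            tzinfo=timezone.utc
        )
        return PolarScan(
            timestamp=ts,
            elevation_deg=float(ds.attrs["elevation_deg"]),
            azimuths_deg=ds["azimuth"].values,
            ranges_m=ds["range"].values,
            fields=fields,
        )


def _read_cfradial(path) -> PolarScan:
    with xr.open_dataset(path, engine="scipy") as ds:
        found = {}
        for alias, canon in FIELD_ALIASES.items():
            if alias in ds.data_vars:
                found[canon] = np.ma.masked_invalid(
                    np.asarray(ds[alias].values, dtype=np.float64)
                )
        _require_fields(found, alias_map=FIELD_ALIASES)
        az = np.asarray(ds["azimuth"].values, dtype=float) % 360.0
        order = np.argsort(az)
        elev = float(np.asarray(ds["elevation"].values).ravel()[0])
        tvals = ds["time"].values
        t0 = np.datetime64(np.min(tvals), "s").astype("datetime64[s]").astype(datetime)
        return PolarScan(
            timestamp=t0.replace(tzinfo=timezone.utc),
            elevation_deg=elev,
            azimuths_deg=az[order],
            ranges_m=np.asarray(ds["range"].values, dtype=float),
            fields={k: v[order] for k, v in found.items()},
        )


def _read_odim(path) -> PolarScan:
    with h5py.File(path, "r") as f:
        where = f["dataset1/where"].attrs
        nbins = int(where["nbins"])
        nrays = int(where["nrays"])
        rscale = float(where["rscale"])
        rstart = float(where.get("rstart", 0.0)) * 1000.0  # km -> m
        elangle = float(where["elangle"])
        ranges = rstart + rscale * (np.arange(nbins) + 0.5)
        azimuths = (np.arange(nrays) + 0.5) * (360.0 / nrays)
        what = f["what"].attrs
        date = _attr_str(what["date"])
        time = _attr_str(what["time"])
        ts = datetime.strptime(date + time, "%Y%m%d%H%M%S").replace(tzinfo=timezone.utc)

        found = {}
        grp = f["dataset1"]
        for key in grp:
            if not key.startswith("data"):
                continue
            sub = grp[key]
            quantity = _attr_str(sub["what"].attrs["quantity"])
            canon = FIELD_ALIASES.get(quantity)
            if canon is None:
                continue
            dwhat = sub["what"].attrs
            gain = float(dwhat.get("gain", 1.0))
            offset = float(dwhat.get("offset", 0.0))
            nodata = dwhat.get("nodata")
            raw = sub["data"][...].astype(np.float64)
            arr = np.ma.masked_invalid(raw)
            if nodata is not None:
                arr = np.ma.masked_values(arr, float(nodata))
            found[canon] = arr * gain + offset
        _require_fields(found, alias_map=FIELD_ALIASES)
        return PolarScan(
            timestamp=ts,
            elevation_deg=elangle,
            azimuths_deg=azimuths,
            ranges_m=ranges,
            fields=found,
        )


def _attr_str(value):
    return value.decode() if isinstance(value, bytes) else str(value)


# -- calibration and masking ----------------------------------------------

def apply_calibration(scan: PolarScan, offsets: CalibrationOffsets) -> PolarScan:
    """Apply additive dB offsets to Z_H and Z_DR; recompute Z_V.

    ``Z_H' = Z_H + zh``, ``Z_DR' = Z_DR + zdr`` and ``Z_V' = Z_H' - Z_DR'``
    so the reflectivity triplet remains algebraically consistent.
    RHO_HV, K_DP and every mask are untouched.  Applying ``(-zh, -zdr)``
    afterwards restores the original scan to machine precision.
    """
    out = scan.copy()
    out.fields["ZH"] = scan.fields["ZH"] + offsets.zh_offset_db
    out.fields["ZDR"] = scan.fields["ZDR"] + offsets.zdr_offset_db
    out.fields["ZV"] = out.fields["ZH"] - out.fields["ZDR"]
    return out


def mask_sector(scan: PolarScan, mask: SectorMask) -> PolarScan:
    """Blank all gates of every ray whose azimuth lies in a masked sector.

    Endpoints are inclusive; an empty mask is the identity.  Masking is
    idempotent.
    """
    if not mask.intervals:
        return scan.copy()
    hit = mask.contains(scan.azimuths_deg)
    out = scan.copy()
    for name, arr in out.fields.items():
        arr[hit, :] = np.ma.masked
    return out
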