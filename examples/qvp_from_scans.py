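"""Build a quasi-vertical profile from a constant-elevation sweep.

Creates one synthetic 3-degree PPI sweep with an azimuth-independent
reflectivity profile, blanks the blocked azimuth sector (45-185 degrees,
as for a radar with obstructed easterly views), and collapses the sweep
into a QVP column.  Because the fields do not vary with azimuth, the
QVP reproduces the per-gate profile exactly — the first sanity check of
the averaging chain.
"""

from datetime import datetime, timezone

import numpy as np

from bioscatter import qvp, radar_io

rng = np.random.default_rng(0)
azimuths = np.arange(360, dtype=float)
ranges = 150.0 + 300.0 * np.arange(100)

# reflectivity decreasing with height, identical on every ray
zh_profile = 10.0 - 0.005 * qvp.beam_height(ranges, 3.0)
zh = np.tile(zh_profile, (360, 1))
scan = radar_io.PolarScan(
    timestamp=datetime(2017, 6, 6, 21, 0, tzinfo=timezone.utc),
    elevation_deg=3.0,
    azimuths_deg=azimuths,
    ranges_m=ranges,
    fields={
        "ZH": zh,
        "ZV": zh - 1.0,
        "ZDR": np.full_like(zh, 1.0),
        "RHOHV": np.full_like(zh, 0.65),
        "KDP": np.full_like(zh, -0.8),
    },
)

masked = radar_io.mask_sector(scan, radar_io.SectorMask(((45, 185),)))
n_masked = int(np.ma.getmaskarray(masked.fields["ZH"]).all(axis=1).sum())
print(f"sector mask removed {n_masked} of 360 rays")

column = qvp.build_qvp(masked, qvp.default_height_grid(), min_count=30)
ok = ~np.ma.getmaskarray(column.values["ZH"])
print(f"QVP column: {ok.sum()} height bins with >= 30 contributing azimuths")
print("lowest bins (height m -> ZH dBZ, contributing azimuth samples):")
for h, v, c in list(zip(column.heights_m[ok], column.values["ZH"][ok],
                        column.counts["ZH"][ok]))[:5]:
    print(f"  {h:7.1f} -> {v:6.2f}  (n={c})")
print(
    "\nthe ZH profile equals the generating per-gate profile because the"
    "\nfields are azimuth-independent; the counts reflect the 219 surviving rays."
)
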