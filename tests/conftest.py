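import numpy as np
import pytest
from datetime import datetime, timezone

from bioscatter import bca, radar_io, synthetic


@pytest.fixture
def simple_scan():
    """A 360-ray x 50-gate scan with random but valid fields."""
    rng = np.random.default_rng(42)
    az = np.arange(360, dtype=float) + 0.5
    rg = 150.0 + 300.0 * np.arange(50)
    zh = rng.normal(0.0, 5.0, (360, 50))
    zdr = rng.normal(1.0, 0.5, (360, 50))
    fields = {
        "ZH": zh,
        "ZV": zh - zdr,  # consistent reflectivity triplet
        "ZDR": zdr,
        "RHOHV": rng.uniform(0.3, 1.0, (360, 50)),
        "KDP": rng.normal(-0.5, 0.5, (360, 50)),
    }
    return radar_io.PolarScan(
        timestamp=datetime(2017, 6, 6, 21, 0, tzinfo=timezone.utc),
        elevation_deg=3.0,
        azimuths_deg=az,
        ranges_m=rg,
        fields=fields,
    )


@pytest.fixture(scope="session")
def fig4_scene():
    """The five-population preset scene used across clustering tests."""
    preset = synthetic.preset_fig4()
    series, truth = synthetic.make_scene(preset, seed=0)
    return preset, series, truth


@pytest.fixture(scope="session")
def fig4_fit(fig4_scene):
    """One fitted clustering of the preset scene (shared; ~1 s)."""
    _, series, truth = fig4_scene
    features = bca.build_features(series)
    tree, labeling = bca.fit(features, bca.BCAConfig(seed=0))
    return series, truth, features, tree, labeling
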