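"""Generate the five-population preset scene and recover its structure.

Builds a 33-night synthetic QVP series containing four bioscatterer
populations plus transient light rain, runs the recursive divisive
clustering, and prints the per-cluster polarimetric means.  With the
default preset the algorithm recovers exactly five clusters: the rain
cluster stands out by its high co-polar correlation (RHO_HV near 0.97)
and near-zero differential reflectivity, while the four bioscatterer
clusters reproduce the generating means (reflectivities between 0 and
-12 dBZ, RHO_HV below 0.7, negative K_DP).
"""

from bioscatter import bca, profiles, synthetic

preset = synthetic.preset_fig4()
series, truth = synthetic.make_scene(preset, seed=0)
print(f"scene: {series.shape[0]} scan times x {series.shape[1]} height bins")

features = bca.build_features(series)
tree, labeling = bca.fit(features, bca.BCAConfig(seed=0))
print(f"clusters found: {len(tree.leaves)} (root split into {tree.root.chosen_k})")

profile = profiles.cluster_summary(labeling, features)
rain = profiles.identify_rain(profile)
print(f"meteorological cluster: {rain}")
print("\nper-cluster means (native units):")
print(profile.means.round(3).to_string())
print(
    "\nZH/ZV in dBZ, ZDR in dB, RHOHV unitless, KDP in deg/km, altitude in m;"
    "\nthe rain cluster is the row with RHOHV > 0.96."
)
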