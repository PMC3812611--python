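"""Simulate a potentiometric measurement campaign and write it to CSV.

Generates the default design — 4 floral classes x 3 physical treatments
x 4 repetitions = 48 assays on a 7-electrode array — where each cell is
a 5-minute potential time series (one reading every 10 s) relaxing to
equilibrium, averaged over its last ten readings.
"""

import sfamtongue as st

config = st.TongueConfig(seed=42)
data = st.generate_dataset(config)

print(f"campaign: {data.n_samples} assays x {data.n_features} electrodes")
print(f"electrodes: {', '.join(data.feature_names)}")
print(f"replicate groups: {', '.join(data.group_order)}")
print(f"first assay (group {data.groups[0]}, class {data.y[0]}):")
for name, mv in zip(data.feature_names, data.X[0]):
    print(f"  {name:8s} {mv:9.2f} mV")

st.write_dataset(data, "campaign.csv", seed=42)
print("\nwrote campaign.csv (group, floral_class, treatment_class, 7 electrode columns)")

# Each printed potential is one electrode's steady-state response to one
# sample; the pattern across the seven electrodes, not any single value,
# is what identifies the honey class.
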