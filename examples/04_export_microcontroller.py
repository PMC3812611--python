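"""Export a trained network for an embedded target and prove parity.

The deployable state is three artifacts: the weight matrix (O x 2d),
the mapfield (O class labels) and the per-electrode min/max used for
normalization.  The standalone predictor re-implements inference from
the exported bundle alone, in float32, the way a C firmware would.
"""

import numpy as np

import sfamtongue as st

data = st.generate_dataset(st.separable_config(seed=7))
train, _ = st.split_train_test(data)
model = st.fit(train, st.SFAMParams(beta=0.8, rho=0.3))

bundle = st.export_model(model)
footprint = st.memory_footprint(model)
print(f"model: d={bundle.d} electrodes, O={bundle.O} categories, M={bundle.n_classes} classes")
print(
    f"footprint: weights {footprint.weights_bytes} B + mapfield "
    f"{footprint.mapfield_bytes} B + min/max {footprint.scaler_bytes} B "
    f"= {footprint.total_bytes} B"
)

with open("sfam_params.h", "w") as fh:
    fh.write(bundle.to_c_header())
with open("sfam_params.txt", "w") as fh:
    fh.write(bundle.to_portable_text())
print("wrote sfam_params.h (C header) and sfam_params.txt (portable bundle)")

rng = np.random.default_rng(0)
probes = rng.uniform(-500, 500, size=(1000, model.d))
mismatches = sum(st.standalone_predict(bundle, x) != model.predict(x) for x in probes)
print(f"standalone-inference parity: {1000 - mismatches}/1000 probes identical")

# A zero mismatch count means the device, holding only the exported
# arrays, will classify exactly like the trained model on the PC.
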