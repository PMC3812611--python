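"""Score held-out replicate groups the way a deployed device is audited.

Trains on groups M1-M8, predicts the 16 assays of M9-M12, and prints
the per-group class vectors, per-group rates, the overall rate and the
confusion matrix.
"""

import numpy as np

import sfamtongue as st

# deliberately hard world: class means only ~10 mV apart against 10 mV
# reading noise, so the test phase shows realistic errors
config = st.TongueConfig(
    class_mean_matrix=5.0 * np.random.default_rng(2).uniform(-1, 1, size=(4, 7)),
    noise_sd=10.0,
    treatment_offset_scale=5.0,
    seed=5,
)
data = st.generate_dataset(config)
train, test = st.split_train_test(data)
model = st.fit(train, st.SFAMParams(beta=0.8, rho=0.3))

report = st.evaluate_model(model, test)
print(report.to_text())

# Each "Class" row lists the predicted floral class of that group's four
# assays in row order (truth is 1 2 3 4); the overall rate is the
# micro-average over all 16 test assays, and confusion rows show where
# each true class's errors went.
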