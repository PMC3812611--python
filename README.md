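# sfamtongue

Simplified Fuzzy ARTMAP (SFAM) for potentiometric electronic tongues,
built for deployment on memory-constrained embedded targets.

An electronic tongue is an array of cross-sensitive electrodes whose
*joint* potential pattern — not any single reading — discriminates
complex liquid samples (the motivating application is authenticating
honey by floral origin with a seven-electrode metallic array). SFAM is
a supervised, incrementally learning classifier well suited to such
data, but its memory cost grows with training: every committed
category stores a weight row of `2d` floats plus a class label. On a
microcontroller that growth matters, so this package treats model
selection as a two-headed objective: maximize the held-out recognition
rate **and** minimize the number of categories (the *mapfield* size
`O`).

## The model

Inputs `a ∈ ℝ^d` (electrode potentials, mV) are min–max normalized and
complement coded, `I = [a, 1 − a] ∈ [0,1]^{2d}`, fixing `|I|₁ = d`.
Each category `j` holds weights `w_j ∈ [0,1]^{2d}` and a class label
via the mapfield. With `∧` the componentwise minimum:

- **choice** (activation): `T_j = |I ∧ w_j|₁ / (α + |w_j|₁)`
- **vigilance** (match): `|I ∧ w_j|₁ / |I|₁ ≥ ρ`
- **learning**: `w_j ← β (I ∧ w_j) + (1 − β) w_j` (fast learning at `β = 1`)

Training searches categories in descending `T`; a label mismatch
triggers *match tracking* (the working vigilance is raised just above
the offending match), and exhaustion commits a new category `w = I`.
Prediction is a pure argmax of `T` — exactly what a firmware routine
can reproduce from three exported artifacts: the weight matrix, the
mapfield, and the per-electrode min/max vectors.

Around the classifier the package provides:

- `model_selection` — (ρ, β) grid sweeps with recognition-rate and
  mapfield matrices, order-k group cross-validation, lexicographic
  best-cell selection (rate ↓, mapfield ↑, ρ ↑, β ↑);
- `variable_selection` — forward / backward / stepwise wrapper
  electrode selection driven by a Parzen-window PNN (or SFAM itself);
- `deploy` — C-header / portable-text export, memory-footprint report,
  and a standalone float32 inference routine proven prediction-identical
  to the source model;
- `synthetic` — a seeded generator of full measurement campaigns
  (per-class electrode means, exponential stabilization over a 5-minute
  assay sampled every 10 s, last-ten-reading averaging, Gaussian
  replicate noise, M1…M12 replicate-group coding).

## Worked example

```python
import sfamtongue as st

data = st.generate_dataset(st.separable_config(seed=7))   # 48 x 7 campaign
train, test = st.split_train_test(data)                   # M1-M8 / M9-M12

plan = st.make_group_kfold(train.groups, 4)               # 24/8 per fold
cv = st.cross_validate_grid(train, st.GridSpec.coarse(), plan)
print(cv.best)
# BestCell(rho=0.1, beta=0.1, rate=100.0, mapfield=4, fold=0)

model = st.fit(train, st.SFAMParams(beta=0.8, rho=0.3))
print(st.evaluate_model(model, test).overall_rate)        # 100.0
print(st.memory_footprint(model).total_bytes)             # 284
```

The best cell reads: with vigilance 0.1 the network covers each of the
4 honey classes with a single category (mapfield 4) and still classifies
every held-out assay correctly — the minimal-memory ideal. The refit
model costs 284 bytes on-device: 4 categories × 14 float32 weights
(224 B) + 4 mapfield labels (4 B) + 7 min/max pairs (56 B).

The `examples/` directory walks each capability end to end: campaign
simulation, grid search, electrode selection, microcontroller export
with parity proof, and test-phase evaluation.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the whole pipeline from scratch at the given seed — simulate the
campaign, sweep the coarse grid under order-4 group CV, run stepwise
electrode selection on the 4-informative/3-dead benchmark, refit at the
selected cell, export the bundle and verify standalone-inference parity
on fresh random probes — printing a summary of what it computed and
writing the result JSON to `--out`.
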