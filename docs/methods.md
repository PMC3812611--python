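# Methods

## The SFAM variant implemented

Several SFAM formulations differ in small details (the handling of the
uncommitted node, the restart after match tracking). This package
fixes one consistent variant and uses it everywhere, including the
naive reference oracle in the test suite:

- **Preprocessing.** Min–max normalization with the scaler fitted on
  training data only; test inputs are clipped into [0, 1]. A constant
  electrode (min == max) maps to 0. This mirrors deployment, where the
  extrema are burned into the device and anything out of range must
  still normalize to something sane. Complement coding follows:
  `I = [a, 1 − a]`, so `|I|₁ = d` exactly.
- **Resonance search.** Candidates are visited in descending choice
  activation `T_j = |I ∧ w_j|₁ / (α + |w_j|₁)` with ties broken toward
  the lowest (oldest) category index. A candidate below the working
  vigilance is skipped; a candidate passing vigilance with the wrong
  label raises the working vigilance to its match value plus ε (match
  tracking) and the search continues down the ranking. The raised
  vigilance is local to the current pattern; the baseline ρ is restored
  for the next presentation.
- **Commitment.** If no candidate resonates with the right label, a new
  category is appended with `w = I` — equivalent to fast-learning an
  uncommitted all-ones node. An optional `max_categories` cap raises a
  capacity error instead of silently saturating.
- **Epochs.** Patterns are presented in dataset row order each epoch
  (an optional seeded shuffle exists but is off, so results are
  reproducible without a seed). Training stops when a full epoch
  changes no weight, or after `max_epochs` (default 100).
- **Test phase.** Pure argmax of `T` over committed categories; no
  vigilance test, so every input receives a class. An opt-in
  `reject_below=ρ` mode returns 0 ("unknown") when the winner's match
  falls below ρ; it is off by default because a deployed classifier of
  this kind always reports a class.

Parameters and defaults: `β` (learning rate, default 1.0 = fast
learning), `ρ` (vigilance, default 0.5), `α = 0.001` (choice; small
values approximate the conservative limit, preferring specific
categories), `ε = 0.001` (match tracking; the smallest nudge that
disqualifies the offending node). α and ε are algorithmic constants of
the SFAM literature rather than quantities with physical units; both
are exposed on `SFAMParams`.

## Model selection

The embedded objective is lexicographic: maximize validation
recognition rate, then minimize mapfield size, then prefer smaller ρ
and smaller β (less vigilant, cheaper models). Only the two leading
criteria are scientifically motivated; the last two are deterministic
tie-breaks.

Grid presets: `coarse` sweeps ρ ∈ {0.1…0.9} × β ∈ {0.1…1.0} at 0.1
steps (9 × 10); `fine` refines ρ ∈ [0.1, 0.3] × β ∈ [0.7, 0.8] at 0.05
steps (5 × 3). Cross-validation is *group-wise*: replicate groups (four
assays measured together) never straddle the train/validation boundary,
and `make_group_kfold` assigns groups to folds as contiguous blocks in
first-appearance order, so an order-4 plan on 8 groups of 4 yields the
classic 24/8 splits. Rates are printed with one decimal.

## Electrode selection

The wrappers are standard greedy searches over column subsets with
fixed tie rules (forward additions prefer the lowest electrode index,
backward removals the highest; the PNN resolves exact score ties toward
the lowest class label). The evaluator is pluggable; the default is a
Probabilistic Neural Network — class score = mean Gaussian kernel
`exp(−‖x − p‖² / 2σ²)` over that class's training patterns — scored by
pooled group-CV recognition rate. σ defaults to 0.1 on [0,1]-normalized
features: about the scale at which same-cluster replicates reinforce
each other while distinct clusters (≳ 0.2 apart after normalization)
contribute almost nothing. A resubstitution mode exists because some
published selection tables do not state which regime produced them; CV
is the default. The scaler is re-fitted per training subset, so no
information leaks across folds or feature subsets.

Stepwise alternates a forward add and a backward drop, accepting a move
only if it *strictly* improves the CV rate; with ties broken as above
the search is fully deterministic.

## The synthetic world

The generator emulates a potentiometric campaign: 4 floral classes × 3
physical treatments × 4 repetitions = 48 assays on 7 electrodes (Au,
Ag, Cu, AgO2, CuO2, AgCl, Ag2CO3 — names only; no electrochemistry is
modeled). Row `s` carries class `(s mod 4) + 1`, treatment
`(s mod 3) + 1`, and group `M(s div 4 + 1)`, reproducing the group
coding in which each group holds one assay per class and each
(class, treatment) pair appears exactly four times. Each assay is

`reading(t) = target · (1 − e^{−t/τ}) + start · e^{−t/τ} + N(0, noise_sd)`

sampled at t = 10, 20, …, 300 s, and the steady state is the mean of
the last ten readings (noise reduction by √10; the Monte-Carlo test
verifies this). The target is `class_mean + treatment_offset`, with
treatment offsets additive per electrode and shared across classes.

Defaults, chosen once as a plausible potentiometric regime and not
revisited: auto class means uniform in ±400 mV (metallic electrodes in
complex media span roughly this range), treatment offsets N(0, 20 mV),
reading noise 5 mV, τ = 30 s (equilibrium within the 5-minute assay;
the last-ten average then carries a relative stabilization residual
below e^{−7}), start potential 0 mV. The real campaign's inter-class
separations and noise magnitudes are unpublished, so these values are a
stated world, not a calibration; one dial (separation vs noise) moves
the pipeline between a 100%-separable regime and a noisy 50–90% regime.

What a green test does establish: the pipeline recovers planted
structure (classes, informative electrodes, minimal category counts)
under the stated world. What it does not: performance on real honey
data, which exhibits drift, fouling, correlated noise and non-Gaussian
replicate variation that this generator deliberately omits.

### The selection benchmark geometry

`selection_benchmark_config()` plants 4 informative electrodes (Au, Ag,
Cu, CuO2) and 3 dead ones. A naive "one-hot mean per class" design
would let 3 electrodes already separate 4 classes, so necessity of all
four cannot be arranged through class means alone (with zero noise,
any tree of "this pair differs only on electrode j" constraints caps at
3 constraints for 4 classes). The construction instead exploits the
treatment offsets: cluster means are `m_class + o_treatment`, and the
geometry is solved so that for each informative electrode j there is a
pair of clusters from *different classes and different treatments*
that coincide on every electrode except j (where they differ by
200 mV). Removing any one of the four therefore merges two clusters of
different classes — with zero noise the merged assays are identical,
the PNN must give them the same prediction, and at least one error per
CV fold follows (the rate is capped at ~91.7%) — while the full quartet
separates all 12 clusters with ≥ 0.19 normalized margin. The four
constraint pairs form a cycle, so the offset vectors are solved from
the cycle-consistency condition `2δ₁ + δ₂ = γ(e₂ − e₁ − e₄)` with
γ = 200 mV. Greedy forward search consequently climbs 75 → 83.3 → 91.7
→ 100% adding exactly the informative quartet, and stepwise terminates
there.

## Deployment export

The bundle carries exactly what inference needs: shapes (d, O, M), the
weight matrix flattened row-major, the mapfield, and the min/max
vectors (interleaved in the C dialect). Values are rendered as the
shortest decimal strings that round-trip through float32, matching a
C-float firmware; labels are one byte (class counts ≤ 255). Array
names and ordering are fixed so emitted headers are byte-stable across
runs, and export → import → export is byte-identical. The standalone
predictor is written as plain loops over the bundle's float32 values —
deliberately mirroring a firmware routine rather than reusing the
training code path — and the parity suite checks it against the source
model on 1000 random probes. The firmware-side normalization uses the
training-set extrema shipped in the bundle, with clipping. The choice
parameter α = 0.001 is compiled into the standalone routine as a
constant, as it would be in firmware.

Footprint accounting is `O·2d·w + O·l + 2d·w` bytes for value width
`w` (default 4) and label width `l` (default 1). Absolute ROM/RAM
figures of any particular toolchain are out of scope.

## Numerical choices and degenerate inputs

- Exact `>=` comparison in the vigilance test; ties in argmax/argsort
  resolve to the lowest index via stable sorting, in both the package
  and the reference oracle.
- Weight updates never grow components, so repeated fast-learning
  passes are idempotent (the stability tests assert a changeless second
  epoch).
- Empty datasets, inconsistent lengths, labels below 1, non-finite
  electrode values, overlapping train/test groups, indivisible fold
  counts and capacity overruns all raise with messages naming the
  offender.
- Oracle-equivalence tests compare the vectorized implementation with a
  pure-Python reference; summation order can differ at the last ulp,
  so weight comparisons use an absolute tolerance of 1e-12 while labels
  and predictions must match exactly.

## Known limitations

- Single-exponential stabilization and i.i.d. Gaussian noise are
  idealizations; no drift, fouling, temperature or reference-electrode
  physics.
- The cyclic class/treatment row coding is balanced only when the class
  and treatment counts are coprime (true for the default 4 × 3).
- Only the float32 export width is implemented; an 8-bit fixed-point
  mode is out of scope.
- Grid sweeps retrain one network per cell; the cost is linear in grid
  size and acceptable at campaign scale (tens of samples), but no
  warm-starting is attempted.
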