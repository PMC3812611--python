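"""Unit and property tests for the SFAM classifier primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays

import sfamtongue as st
from sfamtongue.sfam import CapacityError, choice, learn, match

from conftest import random_training_set

unit = hst.floats(0.0, 1.0, allow_nan=False)


def make_model(d=2, n_classes=4, **params) -> st.SFAMModel:
    scaler = st.FeatureScaler(mins=np.zeros(d), maxs=np.ones(d))
    return st.SFAMModel(
        d=d, params=st.SFAMParams(**params), scaler=scaler, n_classes=n_classes
    )


class TestScalerAndCoding:
    def test_fit_scaler_columnwise_extrema(self):
        s = st.fit_scaler(np.array([[0.0, 10.0], [4.0, 20.0]]))
        assert s.mins.tolist() == [0, 10] and s.maxs.tolist() == [4, 20]

    def test_fit_scaler_single_row_degenerate(self):
        s = st.fit_scaler(np.array([[3.0, -5.0]]))
        assert np.array_equal(s.mins, s.maxs)

    def test_fit_scaler_rejects_bad_input(self):
        with pytest.raises(ValueError):
            st.fit_scaler(np.empty((0, 3)))
        with pytest.raises(ValueError, match=r"column.*\[1\]"):
            st.fit_scaler(np.array([[0.0, np.nan], [1.0, 2.0]]))

    @pytest.mark.parametrize(
        "x, expected",
        [
            ([0.0, 10.0], [0.0, 0.0]),  # at the minima
            ([4.0, 20.0], [1.0, 1.0]),  # at the maxima
            ([9.0, 15.0], [1.0, 0.5]),  # above max -> clipped to 1
            ([-2.0, 5.0], [0.0, 0.0]),  # below min -> clipped to 0
        ],
    )
    def test_normalize(self, x, expected):
        s = st.FeatureScaler(mins=[0.0, 10.0], maxs=[4.0, 20.0])
        assert s.transform(np.array(x)).tolist() == expected

    def test_normalize_constant_column_maps_to_zero(self):
        s = st.FeatureScaler(mins=[5.0, 0.0], maxs=[5.0, 1.0])
        assert s.transform(np.array([5.0, 0.5])).tolist() == [0.0, 0.5]

    def test_normalize_length_mismatch(self):
        s = st.FeatureScaler(mins=[0.0], maxs=[1.0])
        with pytest.raises(ValueError):
            s.transform(np.array([0.1, 0.2]))

    def test_complement_code_definition(self):
        assert st.complement_code(np.array([0.2, 0.7])).tolist() == pytest.approx(
            [0.2, 0.7, 0.8, 0.3]
        )
        assert st.complement_code(np.array([0.0, 1.0])).tolist() == [0, 1, 1, 0]

    def test_complement_code_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            st.complement_code(np.array([1.2]))
        with pytest.raises(ValueError):
            st.complement_code(np.array([]))

    @given(a=arrays(float, 5, elements=unit))
    def test_complement_code_conserves_l1_norm(self, a):
        out = st.complement_code(a)
        assert out.size == 10
        assert out.sum() == pytest.approx(5.0, abs=1e-12)


class TestActivationPrimitives:
    def test_choice_uncommitted_prototype(self):
        I = st.complement_code(np.array([0.3, 0.8]))
        T = choice(I, np.ones(4), alpha=0.001)
        assert T == pytest.approx(2.0 / (0.001 + 4.0))

    def test_choice_self_match(self):
        I = st.complement_code(np.array([0.3, 0.8]))
        assert choice(I, I, 0.001) == pytest.approx(2.0 / (0.001 + 2.0))

    def test_match_extremes(self):
        I = st.complement_code(np.array([0.4, 0.6]))
        assert match(I, I) == pytest.approx(1.0)
        assert match(I, np.zeros(4)) == 0.0

    @given(
        I=arrays(float, 6, elements=unit),
        w=arrays(float, 6, elements=unit),
        beta=hst.floats(0.01, 1.0),
    )
    def test_primitives_match_loop_oracles(self, I, w, beta):
        """choice/match/learn equal their direct element-loop definitions."""
        ov = sum(min(I[k], w[k]) for k in range(6))
        assert choice(I, w, 0.001) == pytest.approx(ov / (0.001 + sum(w)), abs=1e-12)
        if I.sum() > 0:
            assert match(I, w) == pytest.approx(ov / I.sum(), abs=1e-12)
        got = learn(w, I, beta)
        want = [beta * min(I[k], w[k]) + (1 - beta) * w[k] for k in range(6)]
        assert got.tolist() == pytest.approx(want, abs=1e-12)
        assert np.all(got <= w + 1e-15)  # weights never grow

    def test_learn_fast_commit_and_fixed_point(self):
        I = st.complement_code(np.array([0.2, 0.9]))
        assert learn(np.ones(4), I, beta=1.0).tolist() == I.tolist()
        assert learn(I, I, beta=0.5).tolist() == I.tolist()

    def test_learn_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            learn(np.ones(2), np.ones(2), beta=0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            choice(np.ones(4), np.ones(2), 0.001)
        with pytest.raises(ValueError):
            match(np.ones(4), np.ones(2))


class TestTrainPattern:
    def test_first_commit(self):
        m = make_model()
        I = st.complement_code(np.array([0.1, 0.5]))
        assert m.train_pattern(I, 3) is True
        assert m.mapfield_size == 1
        assert m.weights[0].tolist() == I.tolist()
        assert m.mapfield.tolist() == [3]

    def test_repeat_presentation_is_stable(self):
        m = make_model(beta=1.0)
        I = st.complement_code(np.array([0.1, 0.5]))
        m.train_pattern(I, 2)
        assert m.train_pattern(I, 2) is False
        assert m.mapfield_size == 1

    def test_match_tracking_forces_new_node_on_label_conflict(self):
        m = make_model(beta=1.0, rho=0.0)
        I = st.complement_code(np.array([0.4, 0.4]))
        m.train_pattern(I, 1)
        m.train_pattern(I, 2)  # same input, other label: must not recode node 1
        assert m.mapfield_size == 2
        assert m.mapfield.tolist() == [1, 2]

    def test_capacity_error_names_the_cap(self):
        m = make_model(max_categories=1, rho=1.0)
        m.train_pattern(st.complement_code(np.array([0.1, 0.1])), 1)
        with pytest.raises(CapacityError, match="max_categories=1"):
            m.train_pattern(st.complement_code(np.array([0.9, 0.9])), 2)


class TestFitPredict:
    def test_separated_one_per_class(self):
        """Four well-separated patterns, fast learning: one node per class."""
        X = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [100.0, 100.0]])
        data = st.TongueDataset(X=X, y=[1, 2, 3, 4], groups=["M1"] * 4)
        model = st.fit(data, st.SFAMParams(beta=1.0, rho=0.3))
        assert model.mapfield_size == 4
        assert model.predict_batch(X).tolist() == [1, 2, 3, 4]

    def test_identical_rows_one_label_collapse_to_single_node(self):
        X = np.tile([5.0, 7.0], (6, 1))
        data = st.TongueDataset(X=X, y=[2] * 6, groups=["M1"] * 6)
        model = st.fit(data, st.SFAMParams(beta=0.6, rho=0.9))
        assert model.mapfield_size == 1
        assert model.predict(X[0]) == 2

    @pytest.mark.parametrize("rho,beta", [(0.1, 1.0), (0.9, 0.5), (0.5, 0.2)])
    def test_mapfield_bounded_by_n(self, rng, rho, beta):
        data = random_training_set(rng, n=10, d=3)
        model = st.fit(data, st.SFAMParams(beta=beta, rho=rho))
        assert 1 <= model.mapfield_size <= data.n_samples

    def test_training_patterns_recovered_after_fast_learning(self, rng):
        data = random_training_set(rng, n=8, d=3)
        model = st.fit(data, st.SFAMParams(beta=1.0, rho=0.6))
        assert model.predict_batch(data.X).tolist() == data.y.tolist()

    def test_fast_learning_stability_second_pass_changes_nothing(self, rng):
        data = random_training_set(rng, n=10, d=4)
        model = st.fit(data, st.SFAMParams(beta=1.0, rho=0.7))
        coded = [
            st.complement_code(a) for a in model.scaler.transform(data.X)
        ]
        assert not any(
            model.train_pattern(I, int(lab)) for I, lab in zip(coded, data.y)
        )

    def test_determinism_bit_identical_models(self, rng):
        data = random_training_set(rng, n=12, d=4)
        p = st.SFAMParams(beta=0.7, rho=0.4)
        m1, m2 = st.fit(data, p), st.fit(data, p)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.mapfield, m2.mapfield)

    def test_weights_non_increasing_through_training(self, rng):
        """Every committed row only ever shrinks componentwise."""
        data = random_training_set(rng, n=12, d=3)
        model = st.fit(data, st.SFAMParams(beta=0.5, rho=0.5, max_epochs=1))
        before = model.weights.copy()
        coded = [st.complement_code(a) for a in model.scaler.transform(data.X)]
        for I, lab in zip(coded, data.y):
            model.train_pattern(I, int(lab))
        assert np.all(model.weights[: before.shape[0]] <= before + 1e-15)

    def test_predict_untrained_raises(self):
        with pytest.raises(ValueError):
            make_model().predict(np.array([0.5, 0.5]))

    def test_single_category_always_wins(self):
        m = make_model(d=2)
        m.train_pattern(st.complement_code(np.array([0.5, 0.5])), 3)
        for x in np.random.default_rng(0).uniform(-1, 2, size=(20, 2)):
            assert m.predict(x) == 3

    def test_reject_mode_flags_far_inputs(self):
        m = make_model(d=2)
        m.train_pattern(st.complement_code(np.array([0.0, 0.0])), 1)
        assert m.predict(np.array([1.0, 1.0])) == 1
        assert m.predict(np.array([1.0, 1.0]), reject_below=0.9) == 0


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta": 0.0},
            {"beta": 1.5},
            {"rho": -0.1},
            {"rho": 1.01},
            {"alpha": 0.0},
            {"epsilon": -1.0},
            {"max_epochs": 0},
            {"max_categories": 0},
        ],
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            st.SFAMParams(**kwargs)


@settings(max_examples=40, deadline=None)
@given(seed=hst.integers(0, 10_000), beta=hst.sampled_from([0.3, 0.7, 1.0]),
       rho=hst.sampled_from([0.0, 0.4, 0.9]))
def test_fit_agrees_with_naive_reference(seed, beta, rho):
    """Vectorized fit/predict equals the loop-based reference oracle."""
    from reference_sfam import ref_fit, ref_predict

    rng = np.random.default_rng(seed)
    n, d = int(rng.integers(3, 12)), int(rng.integers(1, 5))
    data = random_training_set(rng, n=n, d=d)
    model = st.fit(data, st.SFAMParams(beta=beta, rho=rho))
    ref = ref_fit(data.X.tolist(), data.y.tolist(), beta=beta, rho=rho)
    assert model.mapfield.tolist() == ref["labels"]
    assert np.allclose(model.weights, np.array(ref["weights"]), atol=1e-12, rtol=0)
    queries = rng.uniform(-350, 350, size=(10, d))
    for q in queries:
        assert model.predict(q) == ref_predict(ref, q.tolist())
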