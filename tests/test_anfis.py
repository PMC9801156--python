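"""Unit and property tests for the TSK fuzzy-inference core."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acvoanfis.anfis import (
    AnfisModel,
    FuzzyRule,
    GaussianMF,
    InvalidParameterError,
    ShapeError,
    evaluate,
    evaluate_layers,
    firing_weights,
    grid_model,
    load_model,
    membership,
    model_from_dict,
    model_to_dict,
    normalize_weights,
    rule_output,
    save_model,
    scatter_model,
)


def random_model(rng: np.random.Generator, n_inputs=None, n_rules=None) -> AnfisModel:
    D = n_inputs or int(rng.integers(1, 5))
    R = n_rules or int(rng.integers(1, 5))
    return AnfisModel.from_arrays(
        centers=rng.uniform(0, 1, (R, D)),
        widths=rng.uniform(0.05, 1.0, (R, D)),
        coeffs=rng.uniform(-2, 2, (R, D)),
        biases=rng.uniform(-2, 2, R),
    )


class TestMembership:
    @pytest.mark.parametrize(
        "x, center, width, expected",
        [
            (0.3, 0.3, 0.1, 1.0),                      # peak at the center
            (0.4, 0.3, 0.1, math.exp(-0.5)),           # one width away
            (1.5, 0.5, 1.0, math.exp(-0.5)),
            (0.0, 1.0, 0.5, math.exp(-2.0)),
        ],
    )
    def test_values(self, x, center, width, expected):
        assert membership(x, GaussianMF(center, width)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_symmetry_about_center(self):
        mf = GaussianMF(0.4, 0.2)
        assert membership(0.4 + 0.13, mf) == pytest.approx(
            membership(0.4 - 0.13, mf), abs=0
        )

    def test_width_below_floor_rejected(self):
        with pytest.raises(InvalidParameterError):
            membership(0.0, GaussianMF(0.0, 5e-4))
        with pytest.raises(InvalidParameterError):
            GaussianMF(0.0, -0.1)

    @given(
        x=st.floats(-5, 5),
        c=st.floats(-5, 5),
        shift=st.floats(-3, 3),
        w=st.floats(0.01, 2.0),
    )
    def test_translation_invariance(self, x, c, shift, w):
        assert membership(x, GaussianMF(c, w)) == pytest.approx(
            membership(x + shift, GaussianMF(c + shift, w)), rel=1e-9
        )

    @given(
        c=st.floats(-2, 2),
        w=st.floats(0.05, 2.0),
        d1=st.floats(0.001, 3.0),
        d2=st.floats(0.001, 3.0),
    )
    def test_strictly_decreasing_in_distance(self, c, w, d1, d2):
        near, far = sorted([d1, d2])
        mf = GaussianMF(c, w)
        if near < far:
            assert membership(c + near, mf) > membership(c + far, mf)


class TestFiringAndNormalization:
    def test_product_of_memberships(self):
        # one membership 0.5 on each input -> firing weight 0.25
        w = 1.0 / math.sqrt(2 * math.log(2))  # membership at x=1, c=0 is 0.5
        rule = FuzzyRule(
            (GaussianMF(0.0, w), GaussianMF(0.0, w)), (0.0, 0.0), 0.0
        )
        model = AnfisModel(2, [rule])
        assert firing_weights([1.0, 1.0], model) == pytest.approx([0.25], rel=1e-12)

    def test_all_center_inputs_fire_fully(self):
        model = scatter_model(3, n_rules=2, center=0.5, width=0.2)
        np.testing.assert_allclose(firing_weights([0.5] * 3, model), [1.0, 1.0])

    def test_single_input_equals_membership(self):
        mf = GaussianMF(0.2, 0.3)
        model = AnfisModel(1, [FuzzyRule((mf,), (0.0,), 0.0)])
        assert firing_weights([0.9], model)[0] == pytest.approx(
            membership(0.9, mf), rel=1e-12
        )

    def test_dimension_mismatch(self):
        model = scatter_model(3, n_rules=2)
        with pytest.raises(ShapeError):
            firing_weights([0.1, 0.2], model)

    @pytest.mark.parametrize(
        "w, expected",
        [
            ([1.0, 3.0], [0.25, 0.75]),
            ([0.7, 0.7], [0.5, 0.5]),
            ([0.0, 0.0], [0.5, 0.5]),  # documented uniform fallback
        ],
    )
    def test_normalize_examples(self, w, expected):
        np.testing.assert_allclose(normalize_weights(w), expected, atol=1e-15)

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            normalize_weights([0.5, -0.1])

    @given(
        st.lists(st.floats(0, 1e6), min_size=1, max_size=8).filter(
            lambda w: sum(w) > 0
        )
    )
    def test_normalized_sum_is_one(self, w):
        assert normalize_weights(w).sum() == pytest.approx(1.0, abs=1e-12)


class TestRuleOutputAndEvaluate:
    def test_consequent_examples(self):
        rule = FuzzyRule(
            (GaussianMF(0, 1), GaussianMF(0, 1)), (2.0, 3.0), 1.0
        )
        assert rule_output([1.0, 2.0], rule) == pytest.approx(9.0)
        assert rule_output([0.0, 0.0], rule) == pytest.approx(1.0)
        const = FuzzyRule((GaussianMF(0, 1),), (0.0,), 4.5)
        assert rule_output([123.0], const) == pytest.approx(4.5)

    def test_single_rule_returns_its_consequent(self):
        rule = FuzzyRule((GaussianMF(0.5, 0.2),), (1.5,), -0.5)
        model = AnfisModel(1, [rule])
        assert evaluate([0.8], model) == pytest.approx(rule_output([0.8], rule))

    def test_weighted_combination(self):
        # firing weights (1, 3) and rule outputs (4, 8) -> (4 + 24)/4 = 7
        rules = [
            FuzzyRule((GaussianMF(0.0, 1.0),), (0.0,), 4.0),
            FuzzyRule((GaussianMF(0.0, 1.0),), (0.0,), 8.0),
        ]
        model = AnfisModel(1, rules)
        w = np.array([1.0, 3.0])
        wbar = normalize_weights(w)
        assert float(wbar @ np.array([4.0, 8.0])) == pytest.approx(7.0)
        # equal firing, outputs (0, 1) -> 0.5
        rules = [
            FuzzyRule((GaussianMF(0.5, 0.3),), (0.0,), 0.0),
            FuzzyRule((GaussianMF(0.5, 0.3),), (0.0,), 1.0),
        ]
        assert evaluate([0.2], AnfisModel(1, rules)) == pytest.approx(0.5)

    @given(seed=st.integers(0, 10_000))
    def test_output_within_rule_output_span(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        x = rng.uniform(-1, 2, model.n_inputs)
        f = [rule_output(x, r) for r in model.rules]
        out = evaluate(x, model)
        assert min(f) - 1e-9 <= out <= max(f) + 1e-9

    @given(seed=st.integers(0, 10_000))
    def test_layerwise_equals_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        x = rng.uniform(0, 1, model.n_inputs)
        layers = evaluate_layers(x, model)
        w = layers["O2"]
        f = np.array([rule_output(x, r) for r in model.rules])
        closed = float((w * f).sum() / w.sum())
        assert layers["O5"] == pytest.approx(closed, abs=1e-12)
        assert layers["O5"] == pytest.approx(evaluate(x, model), abs=1e-12)

    def test_predict_matches_scalar_evaluate(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, n_inputs=3, n_rules=4)
        X = rng.uniform(0, 1, (20, 3))
        np.testing.assert_allclose(
            model.predict(X), [evaluate(x, model) for x in X], atol=1e-12
        )


class TestModelStructure:
    def test_grid_partition_rule_count(self):
        model = grid_model(3, m_per_input=2)
        assert model.n_rules == 8
        assert model.partition_scheme == "grid"

    def test_rule_input_count_enforced(self):
        rule = FuzzyRule((GaussianMF(0, 1),), (0.0,), 0.0)
        with pytest.raises(ShapeError):
            AnfisModel(2, [rule])

    def test_consequent_length_enforced(self):
        with pytest.raises(ShapeError):
            FuzzyRule((GaussianMF(0, 1),), (0.0, 1.0), 0.0)

    def test_empty_rule_base_rejected(self):
        with pytest.raises(InvalidParameterError):
            AnfisModel(1, [])

    def test_serialization_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(11)
        model = random_model(rng, n_inputs=4, n_rules=3)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.n_inputs == model.n_inputs
        assert back.partition_scheme == model.partition_scheme
        np.testing.assert_array_equal(back.centers, model.centers)
        np.testing.assert_array_equal(back.widths, model.widths)
        np.testing.assert_array_equal(back.coeffs, model.coeffs)
        np.testing.assert_array_equal(back.biases, model.biases)
        assert model_from_dict(model_to_dict(model)).rules == model.rules
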