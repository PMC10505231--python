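"""The min-max FC estimator: scoring, extreme selection, MLP aggregation,
gradients and training."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_extremes, make_bag

from milfc.estimator import (
    FCEstimatorParams,
    TrainConfig,
    _forward_backward,
    _PARAM_NAMES,
    aggregate_slide_fc,
    estimate_fc,
    init_params,
    mse_loss,
    predict_slide,
    score_patches,
    select_extremes,
    train_fc_estimator,
)




class TestScorePatches:
    def test_zero_weights_give_bias(self, random_params):
        random_params.scorer_weights[:] = 0.0
        random_params.scorer_bias = 0.7
        bag = make_bag(np.random.default_rng(0).normal(size=(5, 8)))
        assert np.allclose(score_patches(bag, random_params), 0.7)

    def test_one_hot_feature(self, random_params):
        e3 = np.zeros((1, 8))
        e3[0, 3] = 1.0
        s = score_patches(make_bag(e3), random_params)
        assert s[0] == pytest.approx(random_params.scorer_weights[3] + random_params.scorer_bias)

    def test_matches_loop_oracle(self, random_params, rng):
        bag = make_bag(rng.normal(size=(50, 8)))
        s = score_patches(bag, random_params)
        oracle = np.array(
            [
                sum(w * x for w, x in zip(random_params.scorer_weights, row))
                + random_params.scorer_bias
                for row in bag.features
            ]
        )
        assert np.allclose(s, oracle, atol=1e-10)

    def test_dimension_mismatch_rejected(self, random_params):
        with pytest.raises(ValueError):
            score_patches(make_bag(np.zeros((3, 5))), random_params)




class TestSelectExtremes:
    def test_simple_example(self):
        assert np.array_equal(select_extremes(np.array([0.9, 0.1, 0.5]), 1), [0.9, 0.1])

    def test_output_length_is_2n(self):
        out = select_extremes(np.random.default_rng(1).normal(size=5000), 100)
        assert out.shape == (200,)

    @pytest.mark.parametrize("P,N", [(5000, 100), (7, 3), (3, 5), (1, 4), (10, 10)])
    def test_matches_brute_force_oracle(self, P, N, rng):
        scores = rng.normal(size=P)
        assert np.array_equal(select_extremes(scores, N), brute_force_extremes(scores, N))

    def test_oracle_agreement_with_ties(self, rng):
        for _ in range(200):
            P = int(rng.integers(1, 40))
            scores = rng.integers(-3, 4, size=P).astype(float)  # many ties
            N = int(rng.integers(1, 12))
            assert np.array_equal(select_extremes(scores, N), brute_force_extremes(scores, N))

    def test_tie_break_prefers_lower_index(self):
        _, idx = select_extremes(np.array([1.0, 1.0, 0.0, 0.0]), 1, return_indices=True)
        assert idx.tolist() == [0, 2]

    def test_uniform_shift_keeps_selection_membership(self, rng):
        scores = rng.normal(size=200)
        _, idx = select_extremes(scores, 20, return_indices=True)
        _, idx_shifted = select_extremes(scores + 5.3, 20, return_indices=True)
        assert np.array_equal(idx, idx_shifted)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_extremes(np.array([]), 3)


class TestAggregate:
    def test_all_zero_params_give_half(self, random_params):
        for name in _PARAM_NAMES:
            arr = getattr(random_params, name)
            if isinstance(arr, np.ndarray):
                arr[:] = 0.0
        random_params.scorer_bias = 0.0
        assert aggregate_slide_fc(np.zeros(6), random_params) == pytest.approx(0.5)

    def test_output_strictly_in_unit_interval(self, rng):
        for _ in range(50):
            params = init_params("1p", 8, 3, rng)
            out = aggregate_slide_fc(rng.normal(scale=10, size=6), params)
            assert 0.0 < out < 1.0

    def test_miniature_longhand_forward_pass(self):
        """Hand-set 2->1->1->1 net checked against longhand arithmetic."""
        params = FCEstimatorParams(
            arm="1p",
            scorer_weights=np.array([1.0]),
            scorer_bias=0.0,
            mlp_w1=np.array([[0.5], [-1.0]]),
            mlp_b1=np.array([0.1]),
            mlp_w2=np.array([[2.0]]),
            mlp_b2=np.array([-0.3]),
            mlp_w3=np.array([[1.5]]),
            mlp_b3=np.array([0.2]),
        )
        x = np.array([0.8, -0.4])
        h1 = 1 / (1 + np.exp(-(0.5 * 0.8 + (-1.0) * (-0.4) + 0.1)))
        h2 = 1 / (1 + np.exp(-(2.0 * h1 - 0.3)))
        expected = 1 / (1 + np.exp(-(1.5 * h2 + 0.2)))
        assert aggregate_slide_fc(x, params) == pytest.approx(expected, abs=1e-12)

    def test_wrong_length_rejected(self, random_params):
        with pytest.raises(ValueError):
            aggregate_slide_fc(np.zeros(5), random_params)


class TestPredictSlide:
    def test_permutation_invariance(self, random_params, rng):
        params19 = init_params("19q", 8, 3, rng)
        for _ in range(10):
            bag = make_bag(rng.normal(size=(40, 8)))
            base = predict_slide(bag, random_params, params19)
            for _ in range(5):
                perm = rng.permutation(40)
                shuffled = make_bag(bag.features[perm])
                pred = predict_slide(shuffled, random_params, params19)
                assert pred.fc_1p_hat == base.fc_1p_hat
                assert pred.fc_19q_hat == base.fc_19q_hat

    def test_patch_scores_align_with_rows(self, random_params, rng):
        params19 = init_params("19q", 8, 3, rng)
        bag = make_bag(rng.normal(size=(12, 8)))
        pred = predict_slide(bag, random_params, params19)
        assert np.allclose(pred.patch_scores_1p, score_patches(bag, random_params))


class TestMSELoss:
    def test_identical_vectors_zero(self):
        assert mse_loss([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_simple_value(self):
        assert mse_loss([0.5], [1.0]) == pytest.approx(0.25)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        oracle = sum((x - y) ** 2 for x, y in zip(a, b)) / 30
        assert mse_loss(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients (no dropout) vs central differences."""
        params = init_params("1p", 6, 2, rng)
        bag = make_bag(rng.normal(size=(9, 6)))
        label = 0.7
        grads = {
            n: np.zeros_like(np.asarray(getattr(params, n), dtype=float)) for n in _PARAM_NAMES
        }
        _forward_backward(params, bag, label, 2, 0.0, rng, grads)

        def loss():
            return (estimate_fc(bag, params)[0] - label) ** 2

        eps = 1e-6
        for name in _PARAM_NAMES:
            if name == "scorer_bias":
                params.scorer_bias += eps
                up = loss()
                params.scorer_bias -= 2 * eps
                down = loss()
                params.scorer_bias += eps
                assert grads[name] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-8)
                continue
            arr = getattr(params, name)
            flat = arr.reshape(-1)
            for j in range(0, flat.size, max(1, flat.size // 5)):
                flat[j] += eps
                up = loss()
                flat[j] -= 2 * eps
                down = loss()
                flat[j] += eps
                num = (up - down) / (2 * eps)
                assert grads[name].reshape(-1)[j] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_loss_decreases_on_single_slide(self, rng):
        bag = make_bag(rng.normal(size=(30, 8)))
        cfg = TrainConfig(N=4, max_epochs=200, n_restarts=1, scorer_init="random",
                          early_stop_patience=200, seed=0)
        params, log = train_fc_estimator([bag], [0.6], config=cfg)
        assert log["train_mse"][-1] < log["train_mse"][0]

    def test_labels_above_one_clipped_with_warning(self, rng):
        bag = make_bag(rng.normal(size=(20, 8)))
        cfg = TrainConfig(N=2, max_epochs=1, n_restarts=1, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            train_fc_estimator([bag, bag], [1.0, 0.6], config=cfg)

    def test_out_of_range_labels_rejected(self, rng):
        bag = make_bag(rng.normal(size=(20, 8)))
        with pytest.raises(ValueError):
            train_fc_estimator([bag], [1.7], config=TrainConfig(N=2, max_epochs=1))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_fc_estimator([], [], config=TrainConfig(N=2, max_epochs=1))

    def test_deterministic_given_seed(self, rng):
        bags = [make_bag(rng.normal(size=(20, 8))) for _ in range(4)]
        labels = [0.5, 0.9, 0.7, 0.6]
        cfg = TrainConfig(N=3, max_epochs=3, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1, _ = train_fc_estimator(bags, labels, config=cfg)
            p2, _ = train_fc_estimator(bags, labels, config=cfg)
        assert np.array_equal(p1.scorer_weights, p2.scorer_weights)
        assert np.array_equal(p1.mlp_w1, p2.mlp_w1)

    def test_recorded_defaults(self):
        cfg = TrainConfig()
        assert cfg.N == 100
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.weight_decay == pytest.approx(5e-4)
        assert cfg.dropout_p == 0.5

    def test_save_load_round_trip(self, trained_1p, tmp_path):
        params, _ = trained_1p
        path = params.save(tmp_path / "m.npz", config=TrainConfig(N=10), extractor_id="synthetic")
        loaded = FCEstimatorParams.load(path)
        assert np.array_equal(loaded.scorer_weights, params.scorer_weights)
        assert np.array_equal(loaded.mlp_w3, params.mlp_w3)
        assert loaded.arm == "1p"


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    scores=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=60),
    N=st.integers(1, 15),
)
def test_select_extremes_property(scores, N):
    """Property: output always 2N long and equal to the sort oracle."""
    scores = np.array(scores)
    out = select_extremes(scores, N)
    assert out.shape == (2 * N,)
    assert np.array_equal(out, brute_force_extremes(scores, N))
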