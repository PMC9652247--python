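"""The three US+SWE combination topologies: arithmetic, contracts, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swefuse import fusion, nn
from swefuse.dcnn import build_dcnn
from swefuse.experiments import reduced_scale_config
from swefuse.fusion import (FusionMethod, build_and_train_parallel,
                            generalized_pool, predict_ensembled,
                            predict_generalized, predict_parallel,
                            train_ensembled, train_generalized)


@pytest.fixture(scope="module")
def tiny_config():
    return reduced_scale_config()


@pytest.fixture(scope="module")
def paired_images():
    """Aligned US/SWE stacks where each modality carries the class signal."""
    rng = np.random.default_rng(7)
    n = 24
    y = np.array([0, 1] * (n // 2))
    base = np.where(y[:, None, None, None] == 1, 0.75, 0.25)
    us = (base + 0.05 * rng.standard_normal((n, 64, 64, 3))).astype(np.float32)
    swe = (base + 0.05 * rng.standard_normal((n, 64, 64, 3))).astype(np.float32)
    return us, y, swe


class _StubModel:
    """Predicts a fixed probability vector; stands in for a trained DCNN."""

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)

    def predict(self, x):
        return self._p[:len(x)]


def _stub_method(name, config, probs_a, probs_b=None):
    models = [_StubModel(probs_a)]
    if probs_b is not None:
        models.append(_StubModel(probs_b))
    return FusionMethod(name=name, config=config, models=models)


class TestGeneralizedArithmetic:
    def test_pooled_training_counts_double(self, tiny_config):
        """522 paired training samples pool to 1044 rows; 112 val pairs to 224."""
        us = np.zeros((522, 1, 1, 1), np.float32)
        y = np.zeros(522)
        x, yy = generalized_pool(us, y, us.copy(), y.copy())
        assert len(x) == 1044 and len(yy) == 1044
        us_v = np.zeros((112, 1, 1, 1), np.float32)
        x_v, _ = generalized_pool(us_v, np.zeros(112), us_v.copy(), np.zeros(112))
        assert len(x_v) == 224

    def test_misaligned_labels_rejected(self):
        us = np.zeros((4, 1, 1, 1), np.float32)
        with pytest.raises(ValueError, match="labels"):
            generalized_pool(us, np.zeros(4), us, np.ones(4))

    @pytest.mark.parametrize("p_us,p_swe,expected",
                             [(0.4, 0.8, 0.6), (0.3, 0.3, 0.3), (0.0, 1.0, 0.5)])
    def test_probability_average(self, tiny_config, p_us, p_swe, expected):
        method = _stub_method("GENERALIZED", tiny_config, None)
        method.models = [_StubModel([p_us])]
        # the single model sees US then SWE; patch to return each in turn
        calls = iter([np.array([p_us]), np.array([p_swe])])
        method.models[0].predict = lambda x: next(calls)
        x = np.zeros((1, 2, 2, 3), np.float32)
        assert predict_generalized(method, x, x)[0] == pytest.approx(expected)


class TestEnsembledArithmetic:
    def test_mean_of_component_probabilities(self, tiny_config):
        method = _stub_method("ENSEMBLED", tiny_config, [0.2, 0.9], [0.6, 0.1])
        x = np.zeros((2, 2, 2, 3), np.float32)
        np.testing.assert_allclose(predict_ensembled(method, x, x), [0.4, 0.5])

    def test_identical_components_degenerate_to_single_model(self, tiny_config):
        p = [0.2, 0.7, 0.55]
        method = _stub_method("ENSEMBLED", tiny_config, p, p)
        x = np.zeros((3, 2, 2, 3), np.float32)
        np.testing.assert_array_equal(predict_ensembled(method, x, x), p)

    def test_wrong_method_kind_rejected(self, tiny_config):
        method = _stub_method("GENERALIZED", tiny_config, [0.5])
        x = np.zeros((1, 2, 2, 3), np.float32)
        with pytest.raises(ValueError, match="GENERALIZED"):
            predict_ensembled(method, x, x)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_average_symmetric_and_bounded(self, p1, p2):
        fused = 0.5 * (p1 + p2)
        assert fused == 0.5 * (p2 + p1)
        assert min(p1, p2) <= fused <= max(p1, p2)


class TestParallel:
    def test_fused_feature_length_is_2048(self, tiny_config):
        trunk_a = build_dcnn(tiny_config, headless=True, seed=0).network
        trunk_b = build_dcnn(tiny_config, headless=True, seed=1).network
        net = nn.TwoStreamNetwork(trunk_a, trunk_b, nn.Dense(1, "sigmoid"), seed=2)
        assert net.fused_features == 2048

    def test_predictions_in_unit_interval_and_deterministic(self, tiny_config,
                                                            paired_images):
        us, y, swe = paired_images
        method = build_and_train_parallel(us, y, swe, us[:6], y[:6], swe[:6],
                                          tiny_config, seed=0, epochs=1)
        p1 = predict_parallel(method, us, swe)
        p2 = predict_parallel(method, us, swe)
        assert p1.shape == (len(us),)
        assert ((0 <= p1) & (p1 <= 1)).all()
        np.testing.assert_array_equal(p1, p2)

    def test_average_combiner_halves_head_width(self, tiny_config, paired_images):
        us, y, swe = paired_images
        method = build_and_train_parallel(us, y, swe, us[:6], y[:6], swe[:6],
                                          tiny_config, seed=0, epochs=1,
                                          combiner="average")
        assert method.network.fused_features == 1024
        p = predict_parallel(method, us, swe)
        assert ((0 <= p) & (p <= 1)).all()

    def test_missing_modality_is_a_pairing_error(self, tiny_config, paired_images):
        us, y, swe = paired_images
        method = build_and_train_parallel(us, y, swe, us[:6], y[:6], swe[:6],
                                          tiny_config, seed=0, epochs=0)
        with pytest.raises(ValueError, match="both US and SWE"):
            predict_parallel(method, us, None)
        with pytest.raises(ValueError, match="aligned"):
            predict_parallel(method, us, swe[:3])


class TestTrainedFusion:
    def test_generalized_trains_on_pooled_stack(self, tiny_config, paired_images):
        us, y, swe = paired_images
        method = train_generalized(us, y, swe, us[:6], y[:6], swe[:6],
                                   tiny_config, seed=0, epochs=2)
        assert method.name == "GENERALIZED"
        assert len(method.models) == 1
        p = predict_generalized(method, us, swe)
        assert ((0 <= p) & (p <= 1)).all()

    def test_ensembled_learns_separable_pairs(self, tiny_config, paired_images):
        us, y, swe = paired_images
        method = train_ensembled(us, y, swe, us[:6], y[:6], swe[:6],
                                 tiny_config, seed=0, epochs=3)
        assert len(method.models) == 2
        p = predict_ensembled(method, us, swe)
        assert np.mean((p >= 0.5) == y) == 1.0

    def test_swapping_modality_model_pairing_preserves_mean(self, tiny_config):
        method = _stub_method("ENSEMBLED", tiny_config, [0.3], [0.8])
        x = np.zeros((1, 2, 2, 3), np.float32)
        forward = predict_ensembled(method, x, x)
        method.models.reverse()
        np.testing.assert_allclose(predict_ensembled(method, x, x), forward)
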