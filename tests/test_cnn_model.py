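import numpy as np
import pytest

from pals import cnn_model, phantom, preprocess
from pals.cnn_model import (
    CNNSegmenter,
    CNNSpec,
    TrainConfig,
    _loss_and_grad,
    _MaxPool2,
    build,
    fit,
    loss,
    segment,
)
from pals.core_io import ABLATED, NON_ABLATED, UNLABELED, LabelMask, ValidationError
from pals.sampling import ClassWeights
from tests.conftest import tiny_config


class TestArchitecture:
    def test_layer1_parameter_count_for_53_channels(self):
        # 3*3*53*53 weights + 53 biases = 25,334
        net = build(CNNSpec(in_channels=53), seed=0)
        assert net.conv1.W.size + net.conv1.b.size == 25334

    def test_hidden_width_is_53_and_head_is_2(self):
        net = build(CNNSpec(in_channels=7), seed=0)
        assert net.conv1.W.shape == (53, 7, 3, 3)
        assert net.conv2.W.shape == (53, 53, 3, 3)
        assert net.conv4.W.shape == (53, 53, 1, 1)
        assert net.conv5.W.shape == (2, 53, 1, 1)

    def test_pooling_chain_matches_floor_division(self):
        # 512 -> 256 -> 128 -> 64 and 339 -> 169 -> 84 -> 42
        x = np.zeros((1, 339, 512), np.float32)
        for expected in ((1, 169, 256), (1, 84, 128), (1, 42, 64)):
            x = _MaxPool2().forward(x, keep=False)
            assert x.shape == expected

    @pytest.mark.parametrize("hw", [(8, 8), (17, 23), (64, 42), (96, 128)])
    def test_shape_contract(self, hw):
        net = build(CNNSpec(in_channels=3), seed=0)
        out = net.forward(np.random.default_rng(0).random((3, *hw), dtype=np.float32))
        assert out.shape == (2, *hw)

    def test_too_small_input_rejected(self):
        net = build(CNNSpec(in_channels=3), seed=0)
        with pytest.raises(ValidationError, match="too small"):
            net.forward(np.zeros((3, 7, 16), np.float32))

    def test_channel_mismatch_rejected(self):
        net = build(CNNSpec(in_channels=3), seed=0)
        with pytest.raises(ValidationError, match="channels"):
            net.forward(np.zeros((4, 16, 16), np.float32))


class TestLoss:
    def test_hand_computed_2x2_toy(self):
        """mask [[ablated, non-ablated], [unlabeled, non-ablated]], uniform
        scores, w_ablated = 3: loss = (3+1+0+1)*ln2 / (3+1+0+1) = ln2."""
        scores = np.zeros((2, 2, 2), np.float32)
        mask = LabelMask(
            np.array([[ABLATED, NON_ABLATED], [UNLABELED, NON_ABLATED]], np.uint8)
        )
        value = loss(scores, mask, ClassWeights(w_ablated=3.0))
        assert value == pytest.approx(np.log(2.0), rel=1e-6)

    def test_perfect_confident_prediction_drives_loss_to_zero(self):
        mask = LabelMask(np.array([[ABLATED, NON_ABLATED]], np.uint8))
        scores = np.zeros((1, 2, 2), np.float32)
        scores[0, 0, 1] = 50.0  # ablated channel high where ablated
        scores[0, 1, 0] = 50.0
        assert loss(scores, mask, ClassWeights(w_ablated=2.0)) < 1e-12

    def test_all_unlabeled_mask_gives_zero_loss(self):
        mask = LabelMask(np.zeros((3, 3), np.uint8))
        scores = np.random.default_rng(0).random((3, 3, 2)).astype(np.float32)
        assert loss(scores, mask, ClassWeights(w_ablated=5.0)) == 0.0

    def test_gradient_zero_at_unlabeled_pixels(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        mask = LabelMask(codes)
        scores = rng.random((2, 6, 6)).astype(np.float32)
        _, grad = _loss_and_grad(scores, mask, ClassWeights(w_ablated=4.0))
        unlabeled = codes == UNLABELED
        assert np.all(grad[:, unlabeled] == 0.0)
        assert np.any(grad[:, ~unlabeled] != 0.0)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(2)
        mask = LabelMask(rng.integers(0, 3, (5, 5)).astype(np.uint8))
        scores = rng.random((5, 5, 2)).astype(np.float32)
        assert loss(scores, mask, ClassWeights(w_ablated=2.0)) >= 0.0

    def test_shape_mismatch_rejected(self):
        mask = LabelMask(np.zeros((3, 3), np.uint8))
        with pytest.raises(ValidationError):
            loss(np.zeros((4, 4, 2), np.float32), mask, ClassWeights(1.0))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Directional-derivative check of the full training path in float64
        (per-entry float32 differences are dominated by rounding noise)."""
        rng = np.random.default_rng(0)
        net = build(CNNSpec(in_channels=2), seed=0)
        for conv in net._convs:
            conv.W = conv.W.astype(np.float64)
            conv.b = conv.b.astype(np.float64)
            conv.dW = np.zeros_like(conv.W)
            conv.db = np.zeros_like(conv.b)
        x = rng.random((2, 8, 8))
        mask = LabelMask(rng.integers(0, 3, (8, 8)).astype(np.uint8))
        weights = ClassWeights(w_ablated=2.5)

        def f():
            return _loss_and_grad(net.forward_logits(x, keep=True), mask, weights)

        _, grad = f()
        net.zero_grad()
        net.backward_logits(grad.astype(np.float64))
        directions = [rng.standard_normal(c.W.shape) for c in net._convs]
        eps = 1e-6
        for conv, d in zip(net._convs, directions):
            analytic = float((conv.dW * d).sum())
            conv.W += eps * d
            lp, _ = f()
            conv.W -= 2 * eps * d
            lm, _ = f()
            conv.W += eps * d
            numeric = (lp - lm) / (2 * eps)
            assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-9)


class TestFit:
    def _tiny_frames(self, n_lesions=(1, 2), seed=0):
        cfg = tiny_config(seed=seed)
        frames = []
        for k in n_lesions:
            f = phantom.make_frame(cfg, k)
            frames.append(preprocess.preprocess_frame(f, cfg.fluence))
        return frames

    def test_loss_trace_decreases(self):
        frames = self._tiny_frames()
        net = build(CNNSpec(in_channels=5), seed=0)
        cfg = TrainConfig(epochs=10, learning_rate=1e-3, batch_size=2,
                          weights=ClassWeights(w_ablated=10.0), seed=0)
        trace = fit(net, frames, cfg)
        assert len(trace) == 10
        assert trace[-1] < trace[0]

    def test_overfit_single_frame(self):
        """Capacity sanity: training F1 approaches 1 on one frame large
        enough for the lesions to survive the 8x downsampling."""
        from pals import evaluation

        cfg = phantom.reduced_config(
            seed=0, grid=tiny_config().grid, noise_sigma=0.05
        )
        frame = preprocess.preprocess_frame(
            phantom.make_frame(cfg, 2), cfg.fluence
        )
        net = build(CNNSpec(in_channels=5), seed=0)
        train_cfg = TrainConfig(epochs=60, learning_rate=2e-3, batch_size=1,
                                weights=ClassWeights(w_ablated=20.0), seed=0)
        fit(net, [frame], train_cfg)
        decision = segment(net, frame).decision
        assert evaluation.frame_f1(decision, frame.mask) > 0.95

    def test_same_seed_identical_weights(self):
        frames = self._tiny_frames()
        runs = []
        for _ in range(2):
            net = build(CNNSpec(in_channels=5), seed=3)
            fit(net, frames, TrainConfig(epochs=3, batch_size=2,
                                         weights=ClassWeights(2.0), seed=3))
            runs.append([conv.W.copy() for conv in net._convs])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_inconsistent_channel_counts_rejected(self):
        from pals.orchestration import subset_frame

        frames = self._tiny_frames()
        frames[1] = subset_frame(frames[1], [690.0, 755.0])
        net = build(CNNSpec(in_channels=5), seed=0)
        with pytest.raises(ValidationError, match="inconsistent"):
            fit(net, frames, TrainConfig(epochs=1, weights=ClassWeights(1.0)))

    def test_empty_frame_list_rejected(self):
        net = build(CNNSpec(in_channels=5), seed=0)
        with pytest.raises(ValidationError):
            fit(net, [], TrainConfig(weights=ClassWeights(1.0)))


class TestSegment:
    def test_result_shapes_and_decision(self, preprocessed_frame):
        net = build(CNNSpec(in_channels=5), seed=0)
        result = segment(net, preprocessed_frame)
        hw = preprocessed_frame.mask.codes.shape
        assert result.decision.shape == hw
        assert result.scores.shape == (*hw, 2)
        np.testing.assert_array_equal(
            result.decision,
            (result.scores[:, :, 1] > result.scores[:, :, 0]).astype(np.uint8),
        )

    def test_requires_preprocessed_frame(self, frame):
        net = build(CNNSpec(in_channels=5), seed=0)
        with pytest.raises(ValidationError, match="preprocessed"):
            segment(net, frame)

    def test_channel_mismatch_rejected(self, preprocessed_frame):
        net = build(CNNSpec(in_channels=4), seed=0)
        with pytest.raises(ValidationError):
            segment(net, preprocessed_frame)

    def test_scores_nonnegative_after_final_relu(self, preprocessed_frame):
        net = build(CNNSpec(in_channels=5), seed=0)
        result = segment(net, preprocessed_frame)
        assert np.all(result.scores >= 0.0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, preprocessed_frame):
        net = build(CNNSpec(in_channels=5), seed=1)
        path = tmp_path / "model.npz"
        net.save(path, wavelengths_nm=preprocessed_frame.cube.grid.values)
        loaded, wavelengths = CNNSegmenter.load(path)
        assert wavelengths == list(preprocessed_frame.cube.grid.values)
        a = segment(net, preprocessed_frame)
        b = segment(loaded, preprocessed_frame)
        np.testing.assert_array_equal(a.scores, b.scores)
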