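"""Unit tests for the predictive-coding network: shapes, error-unit
semantics, training bookkeeping, closed-loop rollout and determinism."""

import numpy as np
import pytest

import predflow as pf
from predflow import _autodiff as ad
from predflow.frames import FrameSequence
from predflow.network import NetworkConfig, PredNet


def _random_frame(rng, shape):
    return rng.uniform(0, 1, shape).astype(np.float32)


class TestArchitecture:
    def test_default_layer_shapes(self):
        """Four-layer default: 3 channels at 120x160 (layer 0) and 48
        channels at 60x80 (layer 1)."""
        net = PredNet(NetworkConfig())
        assert net.R[0].shape == (3, 120, 160)
        assert net.R[1].shape == (48, 60, 80)
        assert net.R[2].shape == (96, 30, 40)
        assert net.R[3].shape == (192, 15, 20)

    def test_error_units_double_channels(self, tiny_config):
        net = PredNet(tiny_config)
        assert net.E[0].shape == (6, 8, 8)

    @pytest.mark.parametrize("n_layers,stacks,shape", [
        (2, (3, 8), (30, 40, 3)),
        (3, (1, 4, 8), (16, 16, 1)),
    ])
    def test_shape_conservation(self, n_layers, stacks, shape):
        """Layer l has stack_sizes[l] channels at input_extent / 2^l."""
        cfg = NetworkConfig(n_layers=n_layers, stack_sizes=stacks, input_shape=shape)
        net = PredNet(cfg)
        for l in range(n_layers):
            h, w = shape[0] // 2 ** l, shape[1] // 2 ** l
            assert net.R[l].shape == (stacks[l], h, w)
            assert net.E[l].shape == (2 * stacks[l], h, w)

    def test_rejects_indivisible_input(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(n_layers=3, stack_sizes=(3, 8, 16), input_shape=(30, 40, 3))

    def test_rejects_channel_mismatch(self):
        with pytest.raises(ValueError, match="channel"):
            NetworkConfig(n_layers=1, stack_sizes=(4,), input_shape=(8, 8, 3))

    def test_state_zeroed_on_init(self, tiny_config):
        net = PredNet(tiny_config)
        for t in net.R + net.C + net.E:
            assert not t.data.any()


class TestStep:
    def test_zero_weights_zero_frame_fixed_point(self, tiny_config):
        net = PredNet(tiny_config)
        net.set_weights({k: np.zeros_like(v) for k, v in net.get_weights().items()})
        pred, errs = net.step(np.zeros((8, 8, 3), np.float32))
        assert not pred.data.any()
        assert errs == [0.0]

    def test_prediction_saturates_in_pixel_range(self, small_config):
        net = PredNet(small_config)
        rng = np.random.default_rng(3)
        for _ in range(5):
            pred, _ = net.step(_random_frame(rng, (16, 16, 3)))
            assert pred.data.min() >= 0.0
            assert pred.data.max() <= small_config.pixel_max

    def test_error_units_nonnegative_every_step(self, small_config):
        net = PredNet(small_config)
        rng = np.random.default_rng(4)
        for _ in range(6):
            net.step(_random_frame(rng, (16, 16, 3)))
            for e in net.E:
                assert (e.data >= 0).all()

    def test_error_matches_elementwise_recomputation(self, tiny_config):
        """E_0 must equal concat(rect(A - Ahat), rect(Ahat - A)) recomputed
        independently from the returned prediction."""
        net = PredNet(tiny_config)
        rng = np.random.default_rng(5)
        frame = _random_frame(rng, (8, 8, 3))
        pred, _ = net.step(frame)
        a = frame.transpose(2, 0, 1)
        expected = np.concatenate(
            [np.maximum(a - pred.data, 0), np.maximum(pred.data - a, 0)])
        np.testing.assert_allclose(net.E[0].data, expected, atol=1e-6)

    def test_rejects_wrong_frame_shape(self, tiny_config):
        net = PredNet(tiny_config)
        with pytest.raises(ValueError, match="shape"):
            net.step(np.zeros((4, 4, 3), np.float32))


class TestTraining:
    def test_one_update_per_batch(self, small_config):
        stream = FrameSequence(np.zeros((40, 16, 16, 3), np.float32))
        net = PredNet(small_config)
        result = net.fit(stream, total_frames=40)
        assert len(result.batch_losses) == 2

    def test_checkpoint_schedule(self, small_config):
        stream = FrameSequence(np.full((60, 16, 16, 3), 0.5, np.float32))
        net = PredNet(small_config)
        result = net.fit(stream, total_frames=60, checkpoint_every=20)
        assert [c.frames_seen for c in result.checkpoints] == [20, 40, 60]
        for c in result.checkpoints:
            assert c.frames_seen % small_config.batch_len == 0

    def test_rejects_short_stream(self, small_config):
        net = PredNet(small_config)
        with pytest.raises(ValueError, match="batch"):
            net.fit(FrameSequence(np.zeros((5, 16, 16, 3), np.float32)))

    def test_rejects_partial_batch_total(self, small_config):
        net = PredNet(small_config)
        stream = FrameSequence(np.zeros((40, 16, 16, 3), np.float32))
        with pytest.raises(ValueError, match="multiple"):
            net.fit(stream, total_frames=30)

    def test_constant_stream_mse_halves(self, small_config):
        """Learning sanity: 200 updates on a constant stream cut the batch
        MSE to under half its initial value."""
        rng = np.random.default_rng(7)
        still = rng.uniform(0, 1, (16, 16, 3)).astype(np.float32)
        stream = FrameSequence(np.broadcast_to(still, (40, 16, 16, 3)).copy())
        net = PredNet(small_config)
        result = net.fit(stream, total_frames=200 * 20)
        assert result.batch_losses[-1] <= 0.5 * result.batch_losses[0]

    def test_seeded_training_reproducible(self, small_config):
        rng = np.random.default_rng(8)
        stream = FrameSequence(rng.uniform(0, 1, (40, 16, 16, 3)).astype(np.float32))
        nets = [PredNet(small_config) for _ in range(2)]
        results = [n.fit(stream, total_frames=200) for n in nets]
        np.testing.assert_array_equal(results[0].batch_losses, results[1].batch_losses)
        w0, w1 = nets[0].get_weights(), nets[1].get_weights()
        for k in w0:
            np.testing.assert_array_equal(w0[k], w1[k])


class TestCheckpointRoundtrip:
    def test_save_load_reproduces_rollout(self, small_config, tmp_path):
        rng = np.random.default_rng(9)
        stream = FrameSequence(rng.uniform(0, 1, (40, 16, 16, 3)).astype(np.float32))
        net = PredNet(small_config)
        result = net.fit(stream, total_frames=40)
        ckpt = result.checkpoints[-1]
        ckpt.save(tmp_path / "ckpt.npz")
        loaded = pf.TrainingCheckpoint.load(tmp_path / "ckpt.npz")
        assert loaded.frames_seen == ckpt.frames_seen
        probe = FrameSequence(rng.uniform(0, 1, (20, 16, 16, 3)).astype(np.float32))
        r1 = PredNet.from_checkpoint(ckpt).rollout_closed_loop(probe)
        r2 = PredNet.from_checkpoint(loaded).rollout_closed_loop(probe)
        for p1, p2 in zip(r1.predictions, r2.predictions):
            np.testing.assert_array_equal(p1, p2)


class _CopyStub(PredNet):
    """Stub predictor that forecasts its most recent input."""

    def __init__(self, config):
        super().__init__(config)
        self._last = None

    def step(self, frame):
        if frame is None:
            frame_chw = self._last
        else:
            frame_chw = self._frame_to_chw(frame)
        self._last = frame_chw
        return ad.Tensor(frame_chw), [0.0]


class _RunningMeanStub(PredNet):
    """Stub predictor that forecasts the mean of all inputs seen."""

    def __init__(self, config):
        super().__init__(config)
        self._seen = []

    def reset_state(self):
        super().reset_state()
        self._seen = []

    def step(self, frame):
        pred = (np.mean(self._seen, axis=0) if self._seen
                else np.zeros(self.config.input_shape, np.float32).transpose(2, 0, 1))
        if frame is None:
            self._seen.append(pred)
        else:
            self._seen.append(self._frame_to_chw(frame))
        return ad.Tensor(pred), [0.0]


class TestRollout:
    def test_copy_stub_static_probe_is_fixed_point(self, tiny_config):
        """A copy predictor fed a static stimulus returns the stimulus
        itself for P1, P2 and P3."""
        still = np.full((8, 8, 3), 0.25, np.float32)
        probe = FrameSequence.from_still(still, n_frames=20)
        rollout = _CopyStub(tiny_config).rollout_closed_loop(probe)
        for p in rollout.predictions:
            np.testing.assert_array_equal(p, still)

    def test_running_mean_stub_feeds_prediction_back(self, tiny_config):
        """P2 must be the mean of the 20 probe frames plus P1 — evidence
        that P1, not a ground-truth 21st frame, enters the context."""
        rng = np.random.default_rng(11)
        frames = rng.uniform(0, 1, (20, 8, 8, 3)).astype(np.float32)
        probe = FrameSequence(frames)
        rollout = _RunningMeanStub(tiny_config).rollout_closed_loop(probe)
        chw = frames.transpose(0, 3, 1, 2)
        p1_expect = chw.mean(axis=0)
        np.testing.assert_allclose(rollout.p1, p1_expect.transpose(1, 2, 0), rtol=1e-5)
        p2_expect = np.concatenate([chw, p1_expect[None]]).mean(axis=0)
        np.testing.assert_allclose(rollout.p2, p2_expect.transpose(1, 2, 0), rtol=1e-5)

    def test_rollout_produces_exactly_k_predictions(self, small_config):
        rng = np.random.default_rng(12)
        probe = FrameSequence(rng.uniform(0, 1, (20, 16, 16, 3)).astype(np.float32))
        rollout = PredNet(small_config).rollout_closed_loop(probe, k=3)
        assert len(rollout.predictions) == 3
        for p in rollout.predictions:
            assert p.shape == (16, 16, 3)

    def test_rollout_deterministic(self, small_config):
        rng = np.random.default_rng(13)
        probe = FrameSequence(rng.uniform(0, 1, (20, 16, 16, 3)).astype(np.float32))
        net = PredNet(small_config)
        r1 = net.rollout_closed_loop(probe)
        r2 = net.rollout_closed_loop(probe)
        for p1, p2 in zip(r1.predictions, r2.predictions):
            np.testing.assert_array_equal(p1, p2)

    def test_rollout_rejects_bad_probe(self, small_config):
        net = PredNet(small_config)
        probe = FrameSequence(np.zeros((10, 16, 16, 3), np.float32))
        with pytest.raises(ValueError, match="20 frames"):
            net.rollout_closed_loop(probe)
        probe20 = FrameSequence(np.zeros((20, 16, 16, 3), np.float32))
        with pytest.raises(ValueError, match="k"):
            net.rollout_closed_loop(probe20, k=0)


class TestActivationDumps:
    def test_channel_images_per_layer(self, tmp_path):
        """Default 4-layer model: 3 images of 120x160 for layer 0 and 48
        images of 60x80 for layer 1."""
        import imageio.v3 as iio

        net = PredNet(NetworkConfig())
        still = np.full((120, 160, 3), 0.5, np.float32)
        probe = FrameSequence.from_still(still, n_frames=20)
        written = net.dump_activations(probe, tmp_path, layers=[0, 1])
        l0 = sorted(tmp_path.glob("layer_0/channel_*.png"))
        l1 = sorted(tmp_path.glob("layer_1/channel_*.png"))
        assert len(l0) == 3 and len(l1) == 48
        img0 = iio.imread(l0[0])
        img1 = iio.imread(l1[0])
        assert img0.shape == (120, 160)
        assert img1.shape == (60, 80)
        assert np.isfinite(img0).all() and img0.min() >= 0 and img0.max() <= 255
        assert len(written) == 51
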