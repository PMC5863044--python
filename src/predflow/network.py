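"""Hierarchical predictive-coding video-prediction network.

The architecture follows the predictive-coding blueprint: each layer holds
recurrent *representation* units (a convolutional LSTM) that emit a local
*prediction*; the prediction is subtracted from the layer's *target* and
the positive and negative halves of the difference, rectified and
concatenated, form the *error* units — the only bottom-up signal.  Layer 0
targets the incoming video frame, so the layer-0 prediction is the model's
next-frame forecast; upper layers target a pooled convolution of the error
below.  Representation updates run top-down (each conv-LSTM sees its own
previous error and the upsampled representation above), error updates run
bottom-up.

Training is unsupervised: the network watches a frame stream in batches of
``batch_len`` consecutive frames and, after each batch, takes one Adam step
on the mean-squared error of the final within-batch frame forecast.  Hidden
state carries across batches; gradients are truncated at batch boundaries.

The model object follows a fit/results convention: :meth:`PredNet.fit`
consumes a stream and returns a :class:`TrainingResult` holding the loss
curve and the requested checkpoints.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from . import _autodiff as ad
from .frames import FrameSequence


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults are the four-layer configuration with 3x3 kernels and
    per-layer channel stacks 3/48/96/192 on 120x160 RGB input.
    """

    n_layers: int = 4
    stack_sizes: tuple[int, ...] = (3, 48, 96, 192)
    filter_size: int = 3
    input_shape: tuple[int, int, int] = (120, 160, 3)  # H, W, C
    pixel_max: float = 1.0
    batch_len: int = 20
    downsample_factor: int = 2
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if len(self.stack_sizes) != self.n_layers:
            raise ValueError(
                f"stack_sizes has {len(self.stack_sizes)} entries for {self.n_layers} layers"
            )
        h, w, c = self.input_shape
        if self.stack_sizes[0] != c:
            raise ValueError("stack_sizes[0] must equal the input channel count")
        div = self.downsample_factor ** (self.n_layers - 1)
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by downsample_factor^(n_layers-1)={div}"
            )

    def layer_shape(self, layer: int) -> tuple[int, int]:
        """Spatial (H, W) extent of layer ``layer``."""
        f = self.downsample_factor ** layer
        return self.input_shape[0] // f, self.input_shape[1] // f

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["stack_sizes"] = tuple(d["stack_sizes"])
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclasses.dataclass
class TrainingCheckpoint:
    """Weight snapshot with provenance (training amount, config, seed)."""

    weights: dict[str, np.ndarray]
    frames_seen: int
    config: NetworkConfig
    seed: int

    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(
            {"frames_seen": self.frames_seen, "seed": self.seed, "config": self.config.to_dict()}
        )
        np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **self.weights)

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "TrainingCheckpoint":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            weights = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(weights, meta["frames_seen"], NetworkConfig.from_dict(meta["config"]),
                   meta["seed"])


@dataclasses.dataclass
class PredictionRollout:
    """Closed-loop forecast frames P1..Pk for one 20-frame probe."""

    inputs: FrameSequence
    predictions: list[np.ndarray]
    frames_seen: int

    @property
    def p1(self) -> np.ndarray:
        return self.predictions[0]

    @property
    def p2(self) -> np.ndarray:
        return self.predictions[1]

    @property
    def p3(self) -> np.ndarray:
        return self.predictions[2]


@dataclasses.dataclass
class TrainingResult:
    """Outcome of :meth:`PredNet.fit`: loss curve and checkpoints."""

    checkpoints: list[TrainingCheckpoint]
    batch_losses: np.ndarray  # MSE of the final within-batch forecast, per update
    frames_seen: int

    def summary(self) -> str:
        lines = ["Predictive network training",
                 f"  updates:       {len(self.batch_losses)}",
                 f"  frames seen:   {self.frames_seen}",
                 f"  checkpoints:   {len(self.checkpoints)}"]
        if len(self.batch_losses):
            lines.append(f"  first/last batch MSE: {self.batch_losses[0]:.5f} / "
                         f"{self.batch_losses[-1]:.5f}")
        return "\n".join(lines)


class PredNet:
    """Predictive-coding model over frame streams.

    Parameters
    ----------
    config:
        Architecture and training hyperparameters.  Weight initialization
        is deterministic in ``config.seed``.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self._init_weights()
        self.reset_state()
        self.frames_seen = 0
        self._optimizer = None

    # ------------------------------------------------------------ weights

    def _layer_lstm_in_channels(self, l: int) -> int:
        cfg = self.config
        c = 2 * cfg.stack_sizes[l] + cfg.stack_sizes[l]  # E_l(prev) + R_l(prev)
        if l < cfg.n_layers - 1:
            c += cfg.stack_sizes[l + 1]  # upsampled R from above
        return c

    def _init_weights(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        k = cfg.filter_size
        self.weights: dict[str, ad.Tensor] = {}

        def conv_param(name, cout, cin):
            fan_in = cin * k * k
            w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
            self.weights[f"{name}.w"] = ad.parameter(w.astype(np.float32), f"{name}.w")
            self.weights[f"{name}.b"] = ad.parameter(np.zeros(cout, np.float32), f"{name}.b")

        for l in range(cfg.n_layers):
            s = cfg.stack_sizes[l]
            conv_param(f"lstm{l}", 4 * s, self._layer_lstm_in_channels(l))
            conv_param(f"pred{l}", s, s)
            if l < cfg.n_layers - 1:
                conv_param(f"target{l + 1}", cfg.stack_sizes[l + 1], 2 * s)
        # forget-gate bias starts positive, standard LSTM practice
        for l in range(cfg.n_layers):
            s = cfg.stack_sizes[l]
            self.weights[f"lstm{l}.b"].data[s : 2 * s] = 1.0

    def parameters(self) -> list[ad.Tensor]:
        return list(self.weights.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.weights.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in self.weights.items():
            v.data = weights[k].astype(np.float32).copy()

    # -------------------------------------------------------------- state

    def reset_state(self) -> None:
        """Zero all representation, cell and error tensors."""
        cfg = self.config
        self.R: list[ad.Tensor] = []
        self.C: list[ad.Tensor] = []
        self.E: list[ad.Tensor] = []
        for l in range(cfg.n_layers):
            h, w = cfg.layer_shape(l)
            s = cfg.stack_sizes[l]
            self.R.append(ad.Tensor(np.zeros((s, h, w), np.float32)))
            self.C.append(ad.Tensor(np.zeros((s, h, w), np.float32)))
            self.E.append(ad.Tensor(np.zeros((2 * s, h, w), np.float32)))

    def detach_state(self) -> None:
        self.R = [r.detach() for r in self.R]
        self.C = [c.detach() for c in self.C]
        self.E = [e.detach() for e in self.E]

    # --------------------------------------------------------------- step

    def _frame_to_chw(self, frame: np.ndarray) -> np.ndarray:
        h, w, c = self.config.input_shape
        frame = np.asarray(frame, dtype=np.float32)
        if frame.shape != (h, w, c):
            raise ValueError(f"frame shape {frame.shape} != input shape {(h, w, c)}")
        return frame.transpose(2, 0, 1)

    def step(self, frame: np.ndarray | None):
        """Advance one time step.

        Top-down sweep updates each conv-LSTM from its previous error and
        the upsampled representation above, then the bottom-up sweep emits
        predictions and recomputes errors.  ``frame`` is the new layer-0
        target; if ``None`` the network runs closed loop, feeding its own
        forecast back in as the target.

        Returns ``(prediction, error_means)``: the layer-0 forecast as an
        HWC array and the mean absolute error activation per layer.
        """
        cfg = self.config
        W = self.weights

        # top-down: update representations from the highest layer downwards
        new_R: list[ad.Tensor] = [None] * cfg.n_layers  # type: ignore
        new_C: list[ad.Tensor] = [None] * cfg.n_layers  # type: ignore
        for l in reversed(range(cfg.n_layers)):
            parts = [self.E[l], self.R[l]]
            if l < cfg.n_layers - 1:
                parts.append(ad.upsample2(new_R[l + 1]))
            gates = ad.conv2d(ad.concat_channels(parts), W[f"lstm{l}.w"], W[f"lstm{l}.b"])
            s = cfg.stack_sizes[l]
            i = ad.sigmoid(ad.slice_channels(gates, 0, s))
            f = ad.sigmoid(ad.slice_channels(gates, s, 2 * s))
            o = ad.sigmoid(ad.slice_channels(gates, 2 * s, 3 * s))
            g = ad.tanh(ad.slice_channels(gates, 3 * s, 4 * s))
            c = ad.add(ad.mul(f, self.C[l]), ad.mul(i, g))
            new_C[l] = c
            new_R[l] = ad.mul(o, ad.tanh(c))

        # bottom-up: predictions, errors, pooled targets
        new_E: list[ad.Tensor] = [None] * cfg.n_layers  # type: ignore
        prediction: ad.Tensor | None = None
        a_l: ad.Tensor | None = None
        for l in range(cfg.n_layers):
            a_hat = ad.conv2d(new_R[l], W[f"pred{l}.w"], W[f"pred{l}.b"])
            if l == 0:
                a_hat = ad.satlu(a_hat, cfg.pixel_max)
                prediction = a_hat
                if frame is None:
                    a_l = a_hat.detach()  # closed loop: own forecast becomes the target
                else:
                    a_l = ad.Tensor(self._frame_to_chw(frame))
            else:
                a_hat = ad.relu(a_hat)
            pos = ad.relu(ad.sub(a_l, a_hat))
            neg = ad.relu(ad.sub(a_hat, a_l))
            new_E[l] = ad.concat_channels([pos, neg])
            if l < cfg.n_layers - 1:
                a_l = ad.maxpool2(
                    ad.relu(ad.conv2d(new_E[l], W[f"target{l + 1}.w"], W[f"target{l + 1}.b"]))
                )

        self.R, self.C, self.E = new_R, new_C, new_E
        if not np.all(np.isfinite(prediction.data)):
            raise FloatingPointError("non-finite activations: training diverged")
        error_means = [float(np.abs(e.data).mean()) for e in new_E]
        return prediction, error_means

    def predict_frame(self, frame: np.ndarray | None) -> np.ndarray:
        """Inference-mode step; returns the forecast as an HWC array."""
        with ad.no_grad():
            pred, _ = self.step(frame)
        return pred.data.transpose(1, 2, 0)

    # ---------------------------------------------------------------- fit

    def fit(
        self,
        stream: FrameSequence,
        total_frames: int | None = None,
        checkpoint_every: int | None = None,
        reset_each_pass: bool = True,
    ) -> TrainingResult:
        """Train on a frame stream, one Adam update per ``batch_len`` frames.

        The stream is consumed sequentially and cycled if ``total_frames``
        exceeds its length; the hidden state carries across consecutive
        batches and resets at each pass through the stream (a video
        boundary).  Each update minimizes the mean-squared error of the
        final within-batch frame forecast against the actual frame.
        """
        cfg = self.config
        if len(stream) < cfg.batch_len:
            raise ValueError("stream shorter than one batch")
        if total_frames is None:
            total_frames = (len(stream) // cfg.batch_len) * cfg.batch_len
        if total_frames % cfg.batch_len:
            raise ValueError("total_frames must be a multiple of batch_len")
        if self._optimizer is None:
            self._optimizer = ad.Adam(self.parameters(), lr=cfg.learning_rate)

        frames = stream.data
        n_avail = (len(frames) // cfg.batch_len) * cfg.batch_len
        checkpoints: list[TrainingCheckpoint] = []
        losses: list[float] = []
        pos = 0
        self.reset_state()
        consumed = 0
        while consumed < total_frames:
            if pos >= n_avail:
                pos = 0
                if reset_each_pass:
                    self.reset_state()
            self.detach_state()
            loss = None
            for t in range(cfg.batch_len):
                frame = frames[pos + t]
                pred, _ = self.step(frame)
                if t == cfg.batch_len - 1:
                    loss = ad.mse(pred, self._frame_to_chw(frame))
            self._optimizer.zero_grad()
            loss.backward()
            self._optimizer.step()
            losses.append(float(loss.data))
            pos += cfg.batch_len
            consumed += cfg.batch_len
            self.frames_seen += cfg.batch_len
            if checkpoint_every and self.frames_seen % checkpoint_every == 0:
                checkpoints.append(self.checkpoint())
        if checkpoint_every is None:
            checkpoints.append(self.checkpoint())
        return TrainingResult(checkpoints, np.asarray(losses), self.frames_seen)

    def checkpoint(self) -> TrainingCheckpoint:
        return TrainingCheckpoint(self.get_weights(), self.frames_seen, self.config,
                                  self.config.seed)

    # ------------------------------------------------------------ rollout

    @classmethod
    def from_checkpoint(cls, ckpt: TrainingCheckpoint) -> "PredNet":
        net = cls(ckpt.config)
        net.set_weights(ckpt.weights)
        net.frames_seen = ckpt.frames_seen
        return net

    def rollout_closed_loop(self, probe: FrameSequence, k: int = 3) -> PredictionRollout:
        """Forecast ``k`` frames beyond a 20-frame probe, feeding each
        forecast back as the next input (P1 becomes frame 21, and so on)."""
        if len(probe) != self.config.batch_len:
            raise ValueError(f"probe must have {self.config.batch_len} frames, got {len(probe)}")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.reset_state()
        with ad.no_grad():
            for frame in probe.data:
                self.step(frame)
            predictions = []
            for _ in range(k):
                pred, _ = self.step(None)
                predictions.append(pred.data.transpose(1, 2, 0).copy())
        return PredictionRollout(probe, predictions, self.frames_seen)

    def dump_activations(
        self,
        probe: FrameSequence,
        out_dir: str | pathlib.Path,
        layers: list[int] | None = None,
        include_errors: bool = False,
    ) -> dict[str, pathlib.Path]:
        """Step through a probe and write each representation channel as a
        normalized grayscale PNG under ``layer_<l>/channel_<c>.png``."""
        import imageio.v3 as iio

        self.reset_state()
        with ad.no_grad():
            for frame in probe.data:
                self.step(frame)
        out_dir = pathlib.Path(out_dir)
        layers = list(range(self.config.n_layers)) if layers is None else layers
        written: dict[str, pathlib.Path] = {}

        def write_stack(tag: str, stack: np.ndarray, l: int):
            d = out_dir / f"layer_{l}"
            d.mkdir(parents=True, exist_ok=True)
            for c_idx in range(stack.shape[0]):
                img = stack[c_idx]
                lo, hi = float(img.min()), float(img.max())
                norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
                p = d / f"{tag}channel_{c_idx:03d}.png"
                iio.imwrite(p, (norm * 255).round().astype(np.uint8))
                written[f"layer_{l}/{tag}channel_{c_idx:03d}"] = p
        for l in layers:
            write_stack("", self.R[l].data, l)
            if include_errors:
                write_stack("error_", self.E[l].data, l)
        return written


def init_network(config: NetworkConfig) -> PredNet:
    """Construct a network with zeroed state and seeded weights."""
    return PredNet(config)
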