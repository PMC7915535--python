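"""The streaming movement-intention decoder.

Two cooperating parts:

* **Encoder** — a 3D-convolutional network that compresses each 0.25 s
  chunk of grid frames (32 timesteps x 10 x 9 cells = 2880 inputs) into a
  single code vector.  Layer order: Conv3d -> ReLU -> BatchNorm -> Conv3d
  -> ReLU -> BatchNorm -> MaxPool3d -> flatten -> Linear -> ReLU ->
  BatchNorm, with valid stride-1 convolutions.  The dense layer's input
  size is always derived from the actual post-pooling shape.
* **Classifier** — a single LSTM (code size in, 64 hidden by default)
  whose hidden state persists across chunks, followed by a linear softmax
  head over the four articulation classes.  One class-probability vector
  is emitted per chunk, i.e. every 0.25 s of signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .epoching import LABELS4
from .nn import LSTM, BatchNorm, Conv3d, Flatten, Linear, MaxPool3d, ReLU, softmax

__all__ = ["EncoderConfig", "ModelConfig", "Encoder", "Classifier", "MovementIntentNet"]


@dataclass(frozen=True)
class EncoderConfig:
    chunk_len: int = 32
    grid_rows: int = 10
    grid_cols: int = 9
    conv1_channels: int = 16
    conv2_channels: int = 32
    conv1_kernel: tuple[int, int, int] = (5, 2, 2)
    conv2_kernel: tuple[int, int, int] = (5, 1, 1)
    pool_kernel: tuple[int, int, int] = (3, 2, 2)
    z_dim: int = 128
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    @property
    def input_features(self) -> int:
        return self.chunk_len * self.grid_rows * self.grid_cols

    def shapes(self) -> dict[str, tuple[int, ...]]:
        """Feature-map shapes through the encoder (channels, t, h, w)."""
        t, h, w = self.chunk_len, self.grid_rows, self.grid_cols
        kt, kh, kw = self.conv1_kernel
        t, h, w = t - kt + 1, h - kh + 1, w - kw + 1
        conv1 = (self.conv1_channels, t, h, w)
        kt, kh, kw = self.conv2_kernel
        t, h, w = t - kt + 1, h - kh + 1, w - kw + 1
        conv2 = (self.conv2_channels, t, h, w)
        pt, ph, pw = self.pool_kernel
        pooled = (self.conv2_channels, t // pt, h // ph, w // pw)
        return {"conv1": conv1, "conv2": conv2, "pooled": pooled}

    @property
    def flat_features(self) -> int:
        return int(np.prod(self.shapes()["pooled"]))


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    lstm_hidden: int = 64
    n_classes: int = 4
    seed: int = 0


class Encoder:
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.layers = [
            Conv3d(1, c.conv1_channels, c.conv1_kernel, rng),
            ReLU(),
            BatchNorm(c.conv1_channels, c.bn_eps, c.bn_momentum),
            Conv3d(c.conv1_channels, c.conv2_channels, c.conv2_kernel, rng),
            ReLU(),
            BatchNorm(c.conv2_channels, c.bn_eps, c.bn_momentum),
            MaxPool3d(c.pool_kernel),
            Flatten(),
            Linear(c.flat_features, c.z_dim, rng),
            ReLU(),
            BatchNorm(c.z_dim, c.bn_eps, c.bn_momentum),
        ]

    def forward(self, chunks: np.ndarray, train: bool = False) -> np.ndarray:
        """(batch, chunk_len, rows, cols) -> (batch, z_dim) codes."""
        c = self.config
        chunks = np.asarray(chunks, dtype=np.float64)
        expect = (c.chunk_len, c.grid_rows, c.grid_cols)
        if chunks.ndim != 4 or chunks.shape[1:] != expect:
            raise ValueError(f"expected chunks of shape (batch, {expect}), got {chunks.shape}")
        x = chunks[:, None]  # single input channel
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dcodes: np.ndarray) -> None:
        dx = dcodes
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Classifier:
    def __init__(self, z_dim: int, hidden: int, n_classes: int, rng: np.random.Generator):
        self.lstm = LSTM(z_dim, hidden, rng)
        self.head = Linear(hidden, n_classes, rng)

    def forward(self, codes: np.ndarray, train: bool = False, state=None) -> np.ndarray:
        """(batch, n_chunks, z_dim) -> (batch, n_chunks, n_classes) logits."""
        hs = self.lstm.forward(codes, train=train, state=state)
        n, t, hid = hs.shape
        logits = self.head.forward(hs.reshape(n * t, hid), train=train)
        return logits.reshape(n, t, -1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        n, t, k = dlogits.shape
        dhs = self.head.backward(dlogits.reshape(n * t, k))
        return self.lstm.backward(dhs.reshape(n, t, -1))

    def parameters(self):
        return self.lstm.parameters() + self.head.parameters()


class MovementIntentNet:
    """Encoder + streaming LSTM classifier over 4 articulation classes."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(config.encoder, rng)
        self.classifier = Classifier(
            config.encoder.z_dim, config.lstm_hidden, config.n_classes, rng
        )
        self.classes = list(LABELS4)[: config.n_classes]

    # ---- forward -----------------------------------------------------
    def forward_epochs(self, epochs: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of epochs, LSTM state reset per epoch.

        epochs : (batch, n_chunks, chunk_len, rows, cols)
        returns (batch, n_chunks, n_classes)
        """
        n, t = epochs.shape[:2]
        codes = self.encoder.forward(epochs.reshape(n * t, *epochs.shape[2:]), train=train)
        return self.classifier.forward(codes.reshape(n, t, -1), train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dcodes = self.classifier.backward(dlogits)
        n, t, z = dcodes.shape
        self.encoder.backward(dcodes.reshape(n * t, z))

    def init_state(self, batch: int = 1):
        return self.classifier.lstm.init_state(batch)

    def classify_step(self, code: np.ndarray, state):
        """One streaming decision from one code vector; returns (probs, state)."""
        code = np.atleast_2d(code)
        h, state = self.classifier.lstm.step(code, state)
        probs = softmax(self.classifier.head.forward(h))
        return np.squeeze(probs, axis=0) if probs.shape[0] == 1 else probs, state

    def stream_classify(self, chunks: np.ndarray, state=None, reset: bool = True) -> np.ndarray:
        """Per-chunk class probabilities for a chunk sequence (T, 32, rows, cols).

        The LSTM state is carried across chunks; ``reset=False`` continues
        from ``state`` (for trial-spanning streams).
        """
        chunks = np.asarray(chunks)
        codes = self.encoder.forward(chunks, train=False)
        if reset or state is None:
            state = self.init_state(1)
        probs = np.empty((len(chunks), self.config.n_classes))
        for i, code in enumerate(codes):
            probs[i], state = self.classify_step(code, state)
        return probs

    # ---- parameter plumbing ------------------------------------------
    def parameters(self):
        return self.encoder.parameters() + self.classifier.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def _state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i:03d}"] = p.value
        bn_idx = 0
        for layer in self.encoder.layers:
            if isinstance(layer, BatchNorm):
                out[f"bn_{bn_idx}_mean"] = layer.running_mean
                out[f"bn_{bn_idx}_var"] = layer.running_var
                bn_idx += 1
        return out

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (.npz) plus a JSON architecture summary."""
        path = Path(path)
        cfg = asdict(self.config)
        np.savez(path, __config__=json.dumps(cfg), **self._state_arrays())
        summary = {
            "config": cfg,
            "shapes": {k: list(v) for k, v in self.config.encoder.shapes().items()},
            "flat_features": self.config.encoder.flat_features,
            "n_parameters": int(sum(p.value.size for p in self.parameters())),
            "classes": self.classes,
        }
        path.with_suffix(".json").write_text(json.dumps(summary, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MovementIntentNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["encoder"] = EncoderConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in cfg["encoder"].items()
                }
            )
            model = cls(ModelConfig(**cfg))
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"param_{i:03d}"]
            bn_idx = 0
            for layer in model.encoder.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = data[f"bn_{bn_idx}_mean"]
                    layer.running_var[...] = data[f"bn_{bn_idx}_var"]
                    bn_idx += 1
        return model

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))
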