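"""Densely connected 1-D convolutional network for fixed-length DNA input.

Topology: a two-convolution stem (64 filters, kernel 3 by default) followed
by average pooling (stride 2), then four dense blocks separated by
transition layers, a flatten, and a single sigmoid unit.  Each dense layer
is the canonical pre-activation bottleneck — BN -> ReLU -> conv(k=1,
4*growth) -> BN -> ReLU -> conv(k=3, growth) — whose output is concatenated
onto everything the block has produced so far.  Transitions compress
channels with a kernel-1 convolution and halve length with average pooling.
"""

from __future__ import annotations

import numpy as np

from .layers import F32, AvgPool1D, BatchNorm1D, Conv1D, Dense, Flatten, ReLU


class DenseLayerBlock:
    """One bottleneck dense layer; forward concatenates input and new features."""

    def __init__(self, c_in: int, growth: int, rng: np.random.Generator):
        self.c_in = c_in
        self.bn1 = BatchNorm1D(c_in)
        self.relu1 = ReLU()
        self.conv1 = Conv1D(c_in, 4 * growth, 1, rng)
        self.bn2 = BatchNorm1D(4 * growth)
        self.relu2 = ReLU()
        self.conv2 = Conv1D(4 * growth, growth, 3, rng)
        self.c_out = c_in + growth

    def sublayers(self):
        return (self.bn1, self.relu1, self.conv1, self.bn2, self.relu2, self.conv2)

    def forward(self, x, training):
        h = x
        for lay in self.sublayers():
            h = lay.forward(h, training)
        return np.concatenate([x, h], axis=2)

    def backward(self, dy):
        dx = dy[:, :, : self.c_in]
        dh = np.ascontiguousarray(dy[:, :, self.c_in :])
        for lay in reversed(self.sublayers()):
            dh = lay.backward(dh)
        return dx + dh


class TransitionBlock:
    """BN -> ReLU -> conv(k=1, compressed channels) -> average pool (stride 2)."""

    def __init__(self, c_in: int, compression: float, rng: np.random.Generator):
        self.c_out = max(1, int(np.floor(c_in * compression)))
        self.layers = (
            BatchNorm1D(c_in),
            ReLU(),
            Conv1D(c_in, self.c_out, 1, rng),
            AvgPool1D(2),
        )

    def sublayers(self):
        return self.layers

    def forward(self, x, training):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class DenseNet1D:
    """The full network; exposes logits, a BCE training step and input gradients."""

    MIN_INPUT_LENGTH = 32

    def __init__(
        self,
        input_length: int,
        stem_filters: int = 64,
        stem_kernel: int = 3,
        block_layers: tuple[int, ...] = (6, 12, 24, 16),
        growth_rate: int = 32,
        transition_compression: float = 0.5,
        seed: int | None = None,
    ):
        if input_length < self.MIN_INPUT_LENGTH:
            raise ValueError(
                f"input_length={input_length} too short for the pooling cascade; "
                f"minimum is {self.MIN_INPUT_LENGTH}"
            )
        if len(block_layers) != 4:
            raise ValueError("block_layers must have exactly 4 entries")
        rng = np.random.default_rng(seed)
        self.input_length = input_length
        self.config = dict(
            input_length=input_length,
            stem_filters=stem_filters,
            stem_kernel=stem_kernel,
            block_layers=list(block_layers),
            growth_rate=growth_rate,
            transition_compression=transition_compression,
        )

        self.stem = (
            Conv1D(4, stem_filters, stem_kernel, rng),
            BatchNorm1D(stem_filters),
            ReLU(),
            Conv1D(stem_filters, stem_filters, stem_kernel, rng),
            BatchNorm1D(stem_filters),
            ReLU(),
            AvgPool1D(2),
        )
        length = input_length // 2
        channels = stem_filters
        self.channel_trace: list[tuple[str, int]] = [("stem", channels)]

        self.blocks: list[object] = []
        for i, n_layers in enumerate(block_layers):
            for _ in range(n_layers):
                dl = DenseLayerBlock(channels, growth_rate, rng)
                self.blocks.append(dl)
                channels = dl.c_out
            self.channel_trace.append((f"denseblock_{i + 1}", channels))
            if i < 3:
                tr = TransitionBlock(channels, transition_compression, rng)
                self.blocks.append(tr)
                channels = tr.c_out
                length //= 2
                self.channel_trace.append((f"transition_{i + 1}", channels))

        self.head = (
            BatchNorm1D(channels),
            ReLU(),
            Flatten(),
            Dense(length * channels, 1, rng),
        )
        self.final_channels = channels
        self.final_length = length

    # ---- plumbing -------------------------------------------------------

    def _all_layers(self):
        yield from self.stem
        for blk in self.blocks:
            yield from blk.sublayers()
        yield from self.head

    def params(self):
        for lay in self._all_layers():
            yield from lay.params()

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat dict of every weight and running statistic, for (de)serialisation."""
        out = {}
        for i, lay in enumerate(self._all_layers()):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                arr = getattr(lay, name, None)
                if arr is not None:
                    out[f"layer{i:03d}.{name}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self._all_layers()):
            for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                arr = getattr(lay, name, None)
                if arr is not None:
                    key = f"layer{i:03d}.{name}"
                    if key not in state or state[key].shape != arr.shape:
                        raise ValueError(f"checkpoint missing or mismatched array {key!r}")
                    setattr(lay, name, state[key].astype(F32).copy())

    # ---- computation ----------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.asarray(x, dtype=F32)
        for lay in self.stem:
            h = lay.forward(h, training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        for lay in self.head:
            h = lay.forward(h, training)
        return h[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = np.empty(len(x), dtype=np.float64)
        for s in range(0, len(x), batch_size):
            z = self.forward_logits(x[s : s + batch_size], training=False)
            out[s : s + batch_size] = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        return out

    def backward_from_logits(self, dlogits: np.ndarray) -> np.ndarray:
        dy = dlogits.astype(F32)[:, None]
        for lay in reversed(self.head):
            dy = lay.backward(dy)
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        for lay in reversed(self.stem):
            dy = lay.backward(dy)
        return dy

    def train_step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward pass; gradients left in place for the optimizer.

        Returns the mean binary cross-entropy of the batch.
        """
        z = self.forward_logits(x, training=True).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        self.backward_from_logits((p - y).astype(F32) / len(y))
        return loss

    def input_gradients(self, x: np.ndarray) -> np.ndarray:
        """d logit / d input, evaluated with inference-mode batch norm."""
        self.forward_logits(x, training=False)
        return self.backward_from_logits(np.ones(len(x), dtype=F32))

    def probability_gradients(self, x: np.ndarray):
        """(probabilities, d probability / d input) in one forward/backward pass."""
        z = self.forward_logits(x, training=False).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        grads = self.backward_from_logits((p * (1 - p)).astype(F32))
        return p, grads
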