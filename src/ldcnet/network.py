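"""LdcNet: a declarative, shape-checked 2D CNN for nodule/nonnodule patches.

The default network is 15 layers: three convolutional blocks (3 convs + one
2x2 max pool each; 64, 128 and 256 filters; 5x5 kernels in the first block,
3x3 after), a 512-wide fully connected layer with dropout, and a final
2-way softmax.  Convolution #1 and every convolution of the last block are
zero-padded so the network stays deep without the spatial size collapsing;
all other convolutions are valid.  Every convolution and the first FC layer
are followed by ReLU.  Variants with 2 or 4 blocks and non-64 input sides
are built from the same arithmetic; :func:`shape_trace` verifies any spec
before a single weight is allocated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2,
    ReLU,
    SoftmaxBinary,
)

__all__ = [
    "NetworkSpec",
    "ShapeTrace",
    "SpecError",
    "default_spec",
    "shape_trace",
    "parameter_count",
    "build",
    "LdcNetModel",
]


class SpecError(ValueError):
    """Raised when a network spec produces an impossible layer arithmetic."""


def _default_filters(n_blocks: int) -> list[int]:
    return [64, 128, 256, 512][:n_blocks]


def _default_kernels(n_blocks: int) -> list[int]:
    return [5] + [3] * (n_blocks - 1)


def _default_padding(n_blocks: int, convs_per_block: int = 3) -> list[bool]:
    """Conv #1 padded; convs of blocks 3+ padded; 2-block nets pad block 2."""
    pad = [False] * (n_blocks * convs_per_block)
    pad[0] = True
    for block in range(n_blocks):
        if (block + 1 >= 3) or (n_blocks == 2 and block == 1):
            for c in range(convs_per_block):
                pad[block * convs_per_block + c] = True
    return pad


@dataclass
class NetworkSpec:
    """Declarative LdcNet configuration; defaults reproduce the 15-layer net."""

    input_side: int = 64
    n_blocks: int = 3
    filters_per_block: list[int] = field(default_factory=lambda: _default_filters(3))
    convs_per_block: int = 3
    kernel_per_block: list[int] = field(default_factory=lambda: _default_kernels(3))
    padding_map: list[bool] | None = None
    fc_width: int = 512
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks not in (2, 3, 4):
            raise SpecError(f"n_blocks must be 2, 3 or 4, got {self.n_blocks}")
        if len(self.filters_per_block) != self.n_blocks:
            raise SpecError("filters_per_block length must equal n_blocks")
        if len(self.kernel_per_block) != self.n_blocks:
            raise SpecError("kernel_per_block length must equal n_blocks")
        if self.padding_map is None:
            self.padding_map = _default_padding(self.n_blocks, self.convs_per_block)
        if len(self.padding_map) != self.n_blocks * self.convs_per_block:
            raise SpecError("padding_map must cover every conv layer")
        if not 0 <= self.dropout_rate < 1:
            raise SpecError("dropout_rate must be in [0, 1)")
        if self.input_side < 20:
            raise SpecError("input_side must be >= 20")

    def to_dict(self) -> dict:
        return {
            "input_side": self.input_side,
            "n_blocks": self.n_blocks,
            "filters_per_block": list(self.filters_per_block),
            "convs_per_block": self.convs_per_block,
            "kernel_per_block": list(self.kernel_per_block),
            "padding_map": list(bool(b) for b in self.padding_map),
            "fc_width": self.fc_width,
            "dropout_rate": self.dropout_rate,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


#: one traced layer: (1-based index, layer type, output dims)
ShapeTrace = list[tuple[int, str, tuple[int, ...]]]


def default_spec(input_side: int = 64, n_blocks: int = 3) -> NetworkSpec:
    """The canonical LdcNet configuration (15 layers at 3 blocks).

    At 64 px the reference padding pattern (conv #1 and the last block)
    applies as-is.  Small input sides would drive the unpadded middle blocks
    to a non-positive size, so padding is forced onto progressively earlier
    blocks — the same move that keeps the 4-block variant workable — until
    the shape arithmetic closes.
    """

    def candidate(pad_from_block: int) -> NetworkSpec:
        pad = [False] * (n_blocks * 3)
        pad[0] = True
        for block in range(n_blocks):
            if (block + 1 >= pad_from_block) or (n_blocks == 2 and block == 1):
                for c in range(3):
                    pad[block * 3 + c] = True
        return NetworkSpec(
            input_side=input_side,
            n_blocks=n_blocks,
            filters_per_block=_default_filters(n_blocks),
            kernel_per_block=_default_kernels(n_blocks),
            padding_map=pad,
        )

    last_error: SpecError | None = None
    for pad_from_block in range(3, 0, -1):
        spec = candidate(pad_from_block)
        try:
            shape_trace(spec)
            return spec
        except SpecError as exc:
            last_error = exc
    raise last_error


def shape_trace(spec: NetworkSpec) -> ShapeTrace:
    """Exact layer-by-layer output dimensions for *spec*.

    Unpadded convs shrink the side by kernel-1; padded convs keep it; pools
    halve with floor division.  Raises :class:`SpecError`, naming the layer,
    if any spatial size would become non-positive.
    """
    trace: ShapeTrace = []
    side = spec.input_side
    index = 0
    conv_idx = 0
    for block in range(spec.n_blocks):
        kernel = spec.kernel_per_block[block]
        channels = spec.filters_per_block[block]
        for _ in range(spec.convs_per_block):
            index += 1
            if not spec.padding_map[conv_idx]:
                side = side - kernel + 1
            conv_idx += 1
            if side <= 0:
                raise SpecError(f"layer {index} (conv) output side {side} <= 0")
            trace.append((index, "conv", (side, side, channels)))
        index += 1
        side = side // 2
        if side <= 0:
            raise SpecError(f"layer {index} (pool) output side {side} <= 0")
        trace.append((index, "pool", (side, side, channels)))
    index += 1
    trace.append((index, "fc", (spec.fc_width,)))
    index += 1
    trace.append((index, "dropout", (spec.fc_width,)))
    index += 1
    trace.append((index, "fc", (spec.n_classes,)))
    return trace


def parameter_count(spec: NetworkSpec) -> int:
    """Closed-form count of trainable parameters (weights + biases)."""
    total = 0
    cin = 1
    for block in range(spec.n_blocks):
        k = spec.kernel_per_block[block]
        cout = spec.filters_per_block[block]
        for _ in range(spec.convs_per_block):
            total += k * k * cin * cout + cout
            cin = cout
    flat_side = next(
        dims[0] for idx, kind, dims in reversed(shape_trace(spec)) if kind == "pool"
    )
    flat = flat_side * flat_side * spec.filters_per_block[-1]
    total += flat * spec.fc_width + spec.fc_width
    total += spec.fc_width * spec.n_classes + spec.n_classes
    return total


class LdcNetModel:
    """A built LdcNet: layer stack plus the softmax head."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        trace = shape_trace(spec)  # validates the arithmetic
        self.layers: list = []
        cin = 1
        conv_idx = 0
        for block in range(spec.n_blocks):
            k = spec.kernel_per_block[block]
            cout = spec.filters_per_block[block]
            for _ in range(spec.convs_per_block):
                pad = (k - 1) // 2 if spec.padding_map[conv_idx] else 0
                self.layers.append(
                    Conv2D(cin, cout, k, pad, rng, input_grad=conv_idx > 0)
                )
                self.layers.append(ReLU())
                cin = cout
                conv_idx += 1
            self.layers.append(MaxPool2())
        flat_side = next(
            dims[0] for idx, kind, dims in reversed(trace) if kind == "pool"
        )
        flat = flat_side * flat_side * cin
        self.layers.append(Flatten())
        self.layers.append(Dense(flat, spec.fc_width, rng))
        self.layers.append(ReLU())
        self.layers.append(Dropout(spec.dropout_rate))
        self.layers.append(Dense(spec.fc_width, spec.n_classes, rng))
        self.head = SoftmaxBinary()

    # -- forward / backward ------------------------------------------------

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1] != self.spec.input_side or x.shape[2] != self.spec.input_side:
            raise ValueError(
                f"patch side {x.shape[1:3]} does not match spec input_side "
                f"{self.spec.input_side}"
            )
        return x

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Positive-class probabilities for a batch (dropout only if *train*)."""
        out = self._prep(x)
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return self.head.forward(out)

    def backward(self, dp: np.ndarray) -> None:
        grad = self.head.backward(dp.astype(np.float32))
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def param_grad_pairs(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    def make_optimizer(self, lr=1e-4, beta1=0.9, beta2=0.999) -> Adam:
        return Adam(self.param_grad_pairs(), lr=lr, beta1=beta1, beta2=beta2)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint weights with the spec embedded (.npz)."""
        import json

        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"p_{i}_{j}"] = p
        np.savez(
            path,
            __spec__=np.frombuffer(
                json.dumps({"spec": self.spec.to_dict(), "seed": self.seed}).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "LdcNetModel":
        import json

        data = np.load(path)
        meta = json.loads(bytes(data["__spec__"]).decode())
        model = cls(NetworkSpec.from_dict(meta["spec"]), meta["seed"])
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"p_{i}_{j}"]
        return model


def build(spec: NetworkSpec, seed: int) -> LdcNetModel:
    """Instantiate a trainable LdcNet with Glorot-uniform init from *seed*."""
    return LdcNetModel(spec, seed)


def predict_proba(model: LdcNetModel, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Deterministic inference-mode nodule probabilities for a patch batch."""
    patches = np.asarray(patches, dtype=np.float32)
    out = []
    for start in range(0, len(patches), batch_size):
        out.append(model.forward(patches[start : start + batch_size], train=False))
    return np.concatenate(out) if out else np.empty(0)
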