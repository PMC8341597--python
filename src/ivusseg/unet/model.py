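"""U-Net encoder–decoder assembly.

Architecture, per encoder level: two 3x3 convolutions (stride 1, 'same'
padding), each followed by ReLU and dropout (rate 0.1 by default); 2x2
max-pooling between levels with the filter count doubling.  The decoder
mirrors the encoder with 2x2 nearest-neighbor upsampling, concatenation of
the matching encoder level's feature map (depth-1 skip connections), and
the same double-convolution block.  A final 1x1 convolution produces the
five class logits; per-pixel softmax gives the class probabilities and the
predicted label is the argmax (ties broken toward the lower class index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ivusseg.masks import LabelMask, N_CLASSES
from ivusseg.unet.layers import Conv1x1, Conv3x3, Dropout, MaxPool2, ReLU, Upsample2


class NetConfigError(ValueError):
    """Invalid network configuration or incompatible input size."""


@dataclass
class NetConfig:
    """U-Net hyperparameters.

    ``depth`` counts encoder levels including the bottleneck, so there are
    ``depth - 1`` poolings and skip connections; inputs must be divisible
    by ``2**(depth-1)``.  ``base_filters`` is the width of the first level
    and doubles at each pooling.
    """

    depth: int = 3
    base_filters: int = 16
    dropout_rate: float = 0.1
    n_classes: int = N_CLASSES
    in_channels: int = 1

    def validate(self) -> None:
        if self.depth < 1:
            raise NetConfigError("depth must be >= 1")
        if self.base_filters < 1:
            raise NetConfigError("base_filters must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise NetConfigError("dropout_rate must be in [0, 1)")
        if self.n_classes != N_CLASSES:
            raise NetConfigError(f"n_classes must be {N_CLASSES}")


class _Block:
    """conv -> relu -> dropout -> conv -> relu -> dropout."""

    def __init__(self, cin: int, cout: int, rate: float, rng: np.random.Generator):
        self.c1 = Conv3x3(cin, cout, rng)
        self.c2 = Conv3x3(cout, cout, rng)
        self.r1, self.r2 = ReLU(), ReLU()
        self.d1, self.d2 = Dropout(rate), Dropout(rate)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        h = self.d1.forward(self.r1.forward(self.c1.forward(x, train), train), train, rng)
        return self.d2.forward(self.r2.forward(self.c2.forward(h, train), train), train, rng)

    def backward(self, d: np.ndarray) -> np.ndarray:
        d = self.c2.backward(self.r2.backward(self.d2.backward(d)))
        return self.c1.backward(self.r1.backward(self.d1.backward(d)))

    @property
    def convs(self) -> list:
        return [self.c1, self.c2]


class UNet:
    """Five-class segmentation U-Net on NumPy tensors."""

    def __init__(self, config: NetConfig, rng_seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(rng_seed)
        d, base = config.depth, config.base_filters
        self.enc: list[_Block] = []
        cin = config.in_channels
        for i in range(d):
            cout = base * 2**i
            self.enc.append(_Block(cin, cout, config.dropout_rate, rng))
            cin = cout
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.ups = [Upsample2() for _ in range(d - 1)]
        self.dec: list[_Block] = []
        for i in reversed(range(d - 1)):
            skip_ch = base * 2**i
            up_ch = base * 2 ** (i + 1)
            self.dec.append(_Block(up_ch + skip_ch, skip_ch, config.dropout_rate, rng))
        self.head = Conv1x1(base, config.n_classes, rng)
        self._skip_channels: list[int] | None = None

    # -- introspection ------------------------------------------------------

    @property
    def conv_layers(self) -> list:
        layers = []
        for b in self.enc + self.dec:
            layers.extend(b.convs)
        layers.append(self.head)
        return layers

    @property
    def n_skip_connections(self) -> int:
        return self.config.depth - 1

    def parameter_count(self) -> int:
        """Total number of trainable weights and biases."""
        return sum(layer.n_params for layer in self.conv_layers)

    # -- passes -------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise NetConfigError(f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        div = 2 ** (self.config.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise NetConfigError(
                f"input size {x.shape[2]}x{x.shape[3]} not divisible by 2^(depth-1) = {div}"
            )

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Class logits (N, 5, H, W) for a batch of frames (N, 1, H, W)."""
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h, train, rng)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, block in enumerate(self.dec):
            i = self.config.depth - 2 - j  # matching encoder level
            h = self.ups[j].forward(h, train)
            h = np.concatenate([skips[i], h], axis=1)
            h = block.forward(h, train, rng)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate the loss gradient; parameter grads land on each layer."""
        d = self.head.backward(dlogits)
        dskips: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.dec))):
            i = self.config.depth - 2 - j
            d = self.dec[j].backward(d)
            sc = self._skip_channels[i]
            dskips[i] = d[:, :sc]
            d = self.ups[j].backward(d[:, sc:])
        for i in reversed(range(len(self.enc))):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)

    # -- inference ----------------------------------------------------------

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Per-class probability maps (5, H, W) for one frame (H, W)."""
        x = np.asarray(image, dtype=np.float32)[None, None]
        logits = self.forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return (ez / ez.sum(axis=1, keepdims=True))[0]

    # -- (de)serialization --------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers:
            out.extend([layer.w.copy(), layer.b.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.conv_layers:
            layer.w = next(it).copy().astype(np.float32)
            layer.b = next(it).copy().astype(np.float32)

    def save(self, path) -> None:
        """Save weights plus architecture hyperparameters as an .npz checkpoint."""
        arrs = {f"p{i}": w for i, w in enumerate(self.get_weights())}
        meta = np.array(
            [self.config.depth, self.config.base_filters, self.config.in_channels], dtype=np.int64
        )
        np.savez(path, _meta=meta, _dropout=np.array([self.config.dropout_rate]), **arrs)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as z:
            depth, base, cin = (int(v) for v in z["_meta"])
            rate = float(z["_dropout"][0])
            n = sum(1 for k in z.files if k.startswith("p"))
            weights = [z[f"p{i}"] for i in range(n)]
        model = cls(NetConfig(depth=depth, base_filters=base, dropout_rate=rate, in_channels=cin))
        model.set_weights(weights)
        return model


def predict(model: UNet, image: np.ndarray, pixel_spacing: float = 0.02) -> tuple[LabelMask, np.ndarray]:
    """Segment one frame: (label mask, per-class probability maps).

    The label is the per-pixel argmax of the softmax probabilities; ties
    break toward the lower class index.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {img.shape}")
    probs = model.predict_probs(img)
    labels = probs.argmax(axis=0).astype(np.uint8)
    return LabelMask(labels, pixel_spacing=pixel_spacing), probs
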