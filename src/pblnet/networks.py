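"""Network architectures: U-shaped segmenter and the tooth-level classifier.

Both segmentation networks (teeth-region ROI and lesion) share one U-shaped
encoder-decoder with skip connections by channel concatenation.  The
tooth-level classifier reuses the segmenter's encoder (downsampling path plus
bottleneck) and attaches a small classification head: two convolution blocks,
global average pooling, and two fully connected layers ending in 32 sigmoid
outputs, one per FDI tooth position.

Because global average pooling is translation invariant while the task is to
assign a lesion to a specific tooth position, the head receives the encoder
features concatenated with two fixed normalized coordinate channels (row and
column in [-1, 1]).  This keeps the transferred encoder untouched while
letting pooled features carry positional information.
"""

from __future__ import annotations

import json
from collections import OrderedDict

import numpy as np

from . import nn
from .nn import Module, Conv2d, Linear, Tensor, concat


class ConvBlock(Module):
    """Two 3x3 conv + ReLU layers."""

    def __init__(self, in_ch, out_ch, rng):
        self.conv1 = Conv2d(in_ch, out_ch, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, rng=rng)

    def __call__(self, x):
        return self.conv2(self.conv1(x).relu()).relu()


class Encoder(Module):
    """Downsampling path plus bottleneck; shared by segmenters and classifiers.

    Level i has base*2**i channels; each level except the bottleneck is
    followed by 2x2 max pooling, so the spatial size shrinks by 2**depth.
    """

    def __init__(self, in_ch=1, base=8, depth=3, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.depth = depth
        self.base = base
        self.blocks = []
        ch = in_ch
        for i in range(depth):
            self.blocks.append(ConvBlock(ch, base * 2 ** i, rng))
            ch = base * 2 ** i
        self.bottleneck = ConvBlock(ch, base * 2 ** depth, rng)

    def __call__(self, x):
        skips = []
        for block in self.blocks:
            x = block(x)
            skips.append(x)
            x = x.maxpool2()
        return self.bottleneck(x), skips

    @property
    def out_channels(self):
        return self.base * 2 ** self.depth


class UNet(Module):
    """U-shaped encoder-decoder emitting a per-pixel probability map."""

    def __init__(self, in_ch=1, base=8, depth=3, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = Encoder(in_ch, base, depth, rng)
        self.up_convs = []
        self.dec_blocks = []
        for i in reversed(range(depth)):
            ch_coarse = base * 2 ** (i + 1)
            ch_fine = base * 2 ** i
            self.up_convs.append(Conv2d(ch_coarse, ch_fine, rng=rng))
            self.dec_blocks.append(ConvBlock(2 * ch_fine, ch_fine, rng))
        self.head = Conv2d(base, 1, kernel=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        x, skips = self.encoder(x)
        for up, dec, skip in zip(self.up_convs, self.dec_blocks,
                                 reversed(skips)):
            x = up(x.upsample2()).relu()
            x = dec(concat(skip, x, axis=1))
        logits = self.head(x)
        return logits.sigmoid().clip(1e-12, 1 - 1e-12)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps for a stack of (H, W) images, without gradients."""
        x = Tensor(np.asarray(images, dtype=np.float64)[:, None])
        return self(x).data[:, 0]

    def encoder_state(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict(
            (k, v) for k, v in self.state_dict().items()
            if k.startswith("encoder."))


class ToothClassifier(Module):
    """Encoder + positional head mapping an ROI crop to 32 tooth scores."""

    N_TEETH = 32

    def __init__(self, in_ch=1, base=8, depth=3, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = Encoder(in_ch, base, depth, rng)
        feat = self.encoder.out_channels
        # two conv blocks over encoder features + coordinate channels
        self.head_conv1 = Conv2d(feat + 2, feat, rng=rng)
        self.head_conv2 = Conv2d(feat, feat, rng=rng)
        self.fc1 = Linear(feat, 2 * feat, rng=rng)
        self.fc2 = Linear(2 * feat, self.N_TEETH, rng=rng)
        self._cam_act: Tensor | None = None
        self._logits: Tensor | None = None

    @staticmethod
    def _coord_channels(n, h, w):
        rows = np.linspace(-1.0, 1.0, h)[:, None].repeat(w, axis=1)
        cols = np.linspace(-1.0, 1.0, w)[None, :].repeat(h, axis=0)
        grid = np.stack([rows, cols])[None]
        return Tensor(np.broadcast_to(grid, (n, 2, h, w)).copy())

    def __call__(self, x: Tensor) -> Tensor:
        feats, _ = self.encoder(x)
        n, _, h, w = feats.shape
        feats = concat(feats, self._coord_channels(n, h, w), axis=1)
        a = self.head_conv1(feats).relu()
        a = self.head_conv2(a).relu()
        self._cam_act = a  # retained for Grad-CAM
        pooled = a.mean(axis=(2, 3))
        hidden = self.fc1(pooled).relu()
        self._logits = self.fc2(hidden)  # pre-sigmoid, retained for Grad-CAM
        return self._logits.sigmoid().clip(1e-12, 1 - 1e-12)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Scores of shape (N, 32) for a stack of (H, W) crops."""
        x = Tensor(np.asarray(images, dtype=np.float64)[:, None])
        return self(x).data

    def load_encoder_state(self, encoder_state):
        """Initialize the encoder from a segmenter's encoder weights.

        Raises ``ValueError`` naming the offending layer on any shape
        mismatch.
        """
        params = dict(self.named_parameters())
        for name, array in encoder_state.items():
            if name not in params:
                raise ValueError(f"no matching classifier layer for {name!r}")
            if params[name].data.shape != np.asarray(array).shape:
                raise ValueError(
                    f"encoder transfer shape mismatch at layer {name!r}: "
                    f"classifier {params[name].data.shape} vs "
                    f"transferred {np.asarray(array).shape}")
            params[name].data = np.asarray(array, dtype=np.float64).copy()

    def encoder_state(self):
        return OrderedDict(
            (k, v) for k, v in self.state_dict().items()
            if k.startswith("encoder."))


# --------------------------------------------------------------------------
# persistence: a single .npz archive of named tensors + a JSON shape manifest


def save_weights(path, state, manifest_path=None):
    np.savez(path, **state)
    if manifest_path is not None:
        manifest = {k: list(v.shape) for k, v in state.items()}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)


def load_weights(path):
    with np.load(path) as data:
        return OrderedDict((k, data[k].copy()) for k in data.files)
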