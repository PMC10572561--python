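"""Deterministic feature extractors for perceptual loss and FID.

The perceptual loss and FID are defined over features from a convolutional
encoder.  The reference construction uses large pretrained classifiers
(VGG19 for the loss, InceptionV3 for FID); here the default is a small
fixed-seed random convolutional encoder shipped with the package, so results
are self-contained and bit-reproducible with no downloads.  Random
convolutional features are a standard stand-in for distributional metrics
(FID computed this way is comparable only within one encoder choice, so
every report records the encoder identity).  The extractor interface is
pluggable: anything exposing ``extract`` (list of feature tensors) and
``identity`` works.
"""

from __future__ import annotations

import numpy as np

from . import engine as E
from . import layers as L
from .engine import Tensor

__all__ = ["SmallConvFeatureExtractor", "IdentityFeatureExtractor",
           "FlattenEncoder", "ConvFeatureEncoder"]


def _to_nchw(image) -> Tensor:
    """Accept (H,W), (C,H,W) or (N,C,H,W) arrays/Tensors → (N,C,H,W) Tensor."""
    t = image if isinstance(image, Tensor) else Tensor(np.asarray(image))
    if t.ndim == 2:
        t = t.reshape((1, 1) + t.shape)
    elif t.ndim == 3:
        t = t.reshape((1,) + t.shape)
    return t


class SmallConvFeatureExtractor:
    """Three fixed-seed convolutional blocks with leaky-rectifier
    activations and stride-2 downsampling; weights are frozen constants."""

    def __init__(self, in_channels: int = 1, base_channels: int = 8,
                 n_blocks: int = 3, seed: int = 12345, gain: float = 2.0):
        rng = np.random.default_rng(seed)
        self.identity = (f"small-conv(base={base_channels},"
                         f"blocks={n_blocks},seed={seed},gain={gain})")
        self.blocks = []
        c_in = in_channels
        for i in range(n_blocks):
            c_out = base_channels * 2 ** i
            conv = L.Conv2d(c_in, c_out, kernel=3, stride=2, padding=1,
                            rng=rng)
            # frozen: features are constants of the metric, not trainable.
            # He-style variance scaling times an amplifying gain, so that
            # feature-space distances are on the scale of the deep
            # pretrained extractors this stands in for.
            std = gain * np.sqrt(2.0 / (c_in * 9))
            conv.weight.requires_grad = False
            conv.weight.data = (conv.weight.data.astype(np.float64)
                                * (std / L.INIT_STD))
            conv.bias.requires_grad = False
            self.blocks.append(conv)
            c_in = c_out

    def extract(self, image) -> list:
        """Feature tensors, one per block, each (N, C_i, H_i, W_i)."""
        h = _to_nchw(image)
        feats = []
        for conv in self.blocks:
            h = conv(h).leaky_relu(0.2)
            feats.append(h)
        return feats


class IdentityFeatureExtractor:
    """Single block returning the image itself; used by the loss oracles."""

    identity = "identity"

    def extract(self, image) -> list:
        return [_to_nchw(image)]


class FlattenEncoder:
    """FID encoder: the raveled image is the feature vector."""

    identity = "flatten"

    def encode(self, image) -> np.ndarray:
        return np.asarray(image, dtype=np.float64).ravel()


class ConvFeatureEncoder:
    """FID encoder built from :class:`SmallConvFeatureExtractor`:
    channel-wise mean and standard deviation of the deepest feature map."""

    def __init__(self, extractor: SmallConvFeatureExtractor | None = None):
        self.extractor = extractor or SmallConvFeatureExtractor()
        self.identity = f"pooled({self.extractor.identity})"

    def encode(self, image) -> np.ndarray:
        with E.no_grad():
            feat = self.extractor.extract(image)[-1].data[0]
        mu = feat.mean(axis=(1, 2))
        sd = feat.std(axis=(1, 2))
        return np.concatenate([mu, sd]).astype(np.float64)
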