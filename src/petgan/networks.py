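"""Generator and discriminator architectures.

The generator is a U-Net encoder–decoder: stride-2 4×4 convolutions down,
mirrored transposed convolutions up, skip connections between matching
resolutions, leaky-rectifier activations in the encoder and rectifiers in
the decoder, and a saturating tanh output so every generated slice lies in
[−1, 1].  The discriminator is a conditional PatchGAN: it sees the early
slice concatenated channel-wise with a real or generated delayed slice and
emits a 2-D grid of raw patch scores (no sigmoid — each adversarial loss
applies its own transform).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import engine as E
from . import layers as L
from .engine import Tensor
from .errors import ConfigError

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "UNetGenerator",
           "PatchDiscriminator", "build_generator", "build_discriminator",
           "receptive_field", "save_checkpoint", "load_checkpoint"]


@dataclass
class GeneratorSpec:
    rows: int = 128
    cols: int = 128
    in_channels: int = 1
    n_down: int = 6            # stride-2 encoder stages
    base_channels: int = 64
    channel_cap: int = 512
    norm_kind: str = "batch"   # batch | instance | none
    skip_connections: bool = True
    # residual=True makes the network predict the uptake CHANGE, added to
    # the input slice and clamped to [−1,1]; the final layer starts at zero
    # so the untrained generator is the identity.  Suited to same-modality
    # translation where most tissue barely changes between time points.
    residual: bool = False

    def validate(self) -> None:
        f = 2 ** self.n_down
        if self.rows % f or self.cols % f:
            raise ConfigError(
                f"input {self.rows}x{self.cols} not divisible by 2^"
                f"{self.n_down}")
        if self.n_down < 1 or self.base_channels < 1:
            raise ConfigError("n_down and base_channels must be >= 1")

    def channels(self) -> list:
        return [min(self.base_channels * 2 ** i, self.channel_cap)
                for i in range(self.n_down)]


@dataclass
class DiscriminatorSpec:
    in_channels: int = 2       # conditional: (early, candidate delayed)
    n_layers: int = 3          # stride-2 convolution stages
    base_channels: int = 64
    channel_cap: int = 512
    norm_kind: str = "batch"
    kernel: int = 4

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")

    def strides(self) -> list:
        # n_layers stride-2 stages, then a stride-1 stage, then the 1-channel
        # stride-1 score convolution
        return [2] * self.n_layers + [1, 1]


class UNetGenerator(L.Module):
    """Encoder–decoder with skip connections mapping [−1,1] slices to
    same-shape [−1,1] slices."""

    def __init__(self, spec: GeneratorSpec, rng=None):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        ch = spec.channels()
        self.enc_convs, self.enc_norms = [], []
        c_in = spec.in_channels
        for i, c in enumerate(ch):
            self.enc_convs.append(L.Conv2d(c_in, c, 4, 2, 1, rng=rng))
            # no norm on the first stage (inputs already in [−1,1]) nor on
            # the bottleneck (its spatial extent may be 1×1)
            use_norm = 0 < i < spec.n_down - 1
            self.enc_norms.append(
                L.make_norm(spec.norm_kind if use_norm else None, c, rng))
            c_in = c
        self.dec_convs, self.dec_norms = [], []
        for i in reversed(range(spec.n_down)):
            c_out = spec.in_channels if i == 0 else ch[i - 1]
            skip = spec.skip_connections and i < spec.n_down - 1
            c_in_dec = ch[i] * (2 if skip else 1)
            self.dec_convs.append(
                L.ConvTranspose2d(c_in_dec, c_out, 4, 2, 1, rng=rng))
            self.dec_norms.append(
                L.make_norm(spec.norm_kind if i > 0 else None, c_out, rng))
        if spec.residual:
            self.dec_convs[-1].weight.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for i, conv in enumerate(self.enc_convs):
            if i > 0:
                h = h.leaky_relu(0.2)
            h = conv(h)
            if self.enc_norms[i] is not None:
                h = self.enc_norms[i](h)
            skips.append(h)
        for j, conv in enumerate(self.dec_convs):
            i = self.spec.n_down - 1 - j        # encoder stage being undone
            if self.spec.skip_connections and i < self.spec.n_down - 1:
                h = E.cat([h, skips[i]], axis=1)
            h = conv(h.relu())
            if self.dec_norms[j] is not None:
                h = self.dec_norms[j](h)
        if self.spec.residual:
            return (x + h).clamp(-1.0, 1.0)
        return h.tanh()


class PatchDiscriminator(L.Module):
    """Conditional PatchGAN emitting a grid of raw patch scores."""

    def __init__(self, spec: DiscriminatorSpec, rng=None):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = rng or np.random.default_rng(0)
        k = spec.kernel
        ch = [min(spec.base_channels * 2 ** i, spec.channel_cap)
              for i in range(spec.n_layers + 1)]
        self.convs, self.norms = [], []
        c_in = spec.in_channels
        for i in range(spec.n_layers):
            self.convs.append(L.Conv2d(c_in, ch[i], k, 2, 1, rng=rng))
            self.norms.append(
                L.make_norm(spec.norm_kind if i > 0 else None, ch[i], rng))
            c_in = ch[i]
        self.convs.append(L.Conv2d(c_in, ch[-1], k, 1, 1, rng=rng))
        self.norms.append(L.make_norm(spec.norm_kind, ch[-1], rng))
        self.score_conv = L.Conv2d(ch[-1], 1, k, 1, 1, rng=rng)

    def forward(self, early: Tensor, candidate: Tensor) -> Tensor:
        if self.spec.in_channels == 2:
            if early.shape[1] != 1 or candidate.shape[1] != 1:
                raise ConfigError(
                    "conditional discriminator expects two single-channel "
                    "inputs")
            h = E.cat([early, candidate], axis=1)
        else:
            h = candidate
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        return self.score_conv(h)


def build_generator(spec: GeneratorSpec, rng=None) -> UNetGenerator:
    return UNetGenerator(spec, rng=rng)


def build_discriminator(spec: DiscriminatorSpec, rng=None) -> PatchDiscriminator:
    return PatchDiscriminator(spec, rng=rng)


def receptive_field(spec: DiscriminatorSpec | None = None, *,
                    strides=None, kernel: int = 4) -> int:
    """Receptive field (pixels) of one patch score, by the standard
    recursion r ← r·s + (k − s) applied from the deepest layer out.

    Either pass a :class:`DiscriminatorSpec` or an explicit stride list.
    """
    if spec is not None:
        strides, kernel = spec.strides(), spec.kernel
    r = 1
    for s in reversed(list(strides)):
        r = r * s + (kernel - s)
    return r


# ---------------------------------------------------------------------------
# checkpoints: spec + weights + seed in one .npz
# ---------------------------------------------------------------------------

_SPEC_KINDS = {"generator": GeneratorSpec, "discriminator": DiscriminatorSpec}


def save_checkpoint(path: str, model: L.Module, seed: int | None = None,
                    extra: dict | None = None) -> None:
    kind = ("generator" if isinstance(model, UNetGenerator)
            else "discriminator")
    meta = {"kind": kind, "spec": asdict(model.spec), "seed": seed,
            "extra": extra or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str):
    """Return (model, meta) rebuilt from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec = _SPEC_KINDS[meta["kind"]](**meta["spec"])
    model = (UNetGenerator(spec) if meta["kind"] == "generator"
             else PatchDiscriminator(spec))
    model.load_state_dict(state)
    return model, meta
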