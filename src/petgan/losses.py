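"""Adversarial and image-similarity objectives.

Three adversarial losses (cross-entropy GAN, WGAN with gradient penalty,
least-squares GAN), two similarity losses (L1 and perceptual = weighted
content + style), and the total generator objective

    L_total = L_adv(G, D) + λ_sim · L_sim(G)

with the reference weights λ_L1 = 200, λ_perceptual = 0.1, λ_gp = 10 and all
per-block content/style weights 1.  Patch scores from the discriminator are
reduced by arithmetic mean before expectations.  The vanilla GAN generator
uses the saturating objective by default (minimize E[log(1−σ(D(x̃)))]); a
non-saturating switch is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as E
from .engine import Tensor
from .errors import ConfigError

__all__ = ["LossWeights", "LossConfig", "make_loss_config", "LOSS_NAMES",
           "gan_loss_d", "gan_loss_g", "wgan_gp_loss_d", "wgan_loss_g",
           "lsgan_loss_d", "lsgan_loss_g", "l1_loss", "gram_matrix",
           "content_loss", "style_loss", "perceptual_loss",
           "total_generator_loss"]


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_nonempty(*scores):
    for s in scores:
        if s.size == 0:
            raise ConfigError("empty score batch")


# ---------------------------------------------------------------------------
# adversarial losses
# ---------------------------------------------------------------------------

def gan_loss_d(real_scores, fake_scores) -> Tensor:
    """Cross-entropy discriminator loss on raw patch scores:
    −E[log σ(D(x))] − E[log(1 − σ(D(x̃)))]."""
    r, f = _t(real_scores), _t(fake_scores)
    _check_nonempty(r, f)
    return -(r.logsigmoid().mean()) - ((-f).logsigmoid().mean())


def gan_loss_g(fake_scores, saturating: bool = True) -> Tensor:
    """Vanilla GAN generator term.  Saturating (the literal minimax form):
    minimize E[log(1 − σ(D(x̃)))]; non-saturating: minimize −E[log σ(D(x̃))]."""
    f = _t(fake_scores)
    _check_nonempty(f)
    if saturating:
        return (-f).logsigmoid().mean()
    return -(f.logsigmoid().mean())


def wgan_gp_loss_d(D, real, fake, lambda_gp: float = 10.0, rng=None,
                   cond=None):
    """Wasserstein critic loss with gradient penalty.

    E[D(x̃)] − E[D(x)] + λ_gp·E[(‖∇_x̂ D(x̂)‖₂ − 1)²], where x̂ interpolates
    real and generated images with per-sample ε ~ Uniform(0,1).  ``D`` is a
    callable; with ``cond`` given it is called as ``D(cond, x)`` (conditional
    critic) and the penalty is taken with respect to the interpolated
    candidate only.  Returns (total loss, dict of components).
    """
    if lambda_gp < 0:
        raise ConfigError(f"lambda_gp must be >= 0, got {lambda_gp}")
    rng = rng or np.random.default_rng(0)
    real, fake = _t(real), _t(fake)

    def call(x):
        return D(cond, x) if cond is not None else D(x)

    d_real = call(real).mean()
    d_fake = call(fake.detach() if fake.requires_grad else fake).mean()
    w_term = d_fake - d_real

    n = real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=(n,) + (1,) * (real.ndim - 1))
    x_hat = Tensor((eps * real.data + (1.0 - eps) * fake.data)
                   .astype(real.dtype), requires_grad=True)
    scores = call(x_hat)
    g = E.grad(scores.sum(), x_hat, create_graph=True)
    per_sample = (g ** 2.0).sum(axis=tuple(range(1, real.ndim))) ** 0.5
    penalty = ((per_sample - 1.0) ** 2.0).mean() * lambda_gp
    total = w_term + penalty
    return total, {"wasserstein": w_term, "gradient_penalty": penalty}


def wgan_loss_g(fake_scores) -> Tensor:
    """Generator term of the Wasserstein objective: −E[D(x̃)]."""
    f = _t(fake_scores)
    _check_nonempty(f)
    return -(f.mean())


def lsgan_loss_d(real_scores, fake_scores) -> Tensor:
    """Least-squares discriminator loss: ½E[D(x̃)²] + ½E[(D(x)−1)²]."""
    r, f = _t(real_scores), _t(fake_scores)
    _check_nonempty(r, f)
    return 0.5 * (f ** 2.0).mean() + 0.5 * ((r - 1.0) ** 2.0).mean()


def lsgan_loss_g(fake_scores) -> Tensor:
    """Least-squares generator loss: ½E[(D(x̃)−1)²]."""
    f = _t(fake_scores)
    _check_nonempty(f)
    return 0.5 * ((f - 1.0) ** 2.0).mean()


# ---------------------------------------------------------------------------
# similarity losses
# ---------------------------------------------------------------------------

def l1_loss(generated, target) -> Tensor:
    """Mean absolute voxel difference."""
    g, t = _t(generated), _t(target)
    if g.shape != t.shape:
        raise ConfigError(f"shape mismatch {g.shape} vs {t.shape}")
    return (g - t).abs().mean()


def gram_matrix(feature: Tensor) -> Tensor:
    """Normalized Gram matrix of a (C,H,W) feature:
    Gr[i,j] = Σ_{h,w} F[i,h,w]·F[j,h,w] / (C·H·W)."""
    f = _t(feature)
    if f.ndim == 4:            # single-image batch
        f = f.reshape(f.shape[1:])
    c, h, w = f.shape
    flat = f.reshape((c, h * w))
    return flat @ flat.transpose((1, 0)) * (1.0 / (c * h * w))


def content_loss(gen_image, target_image, extractor, w_content=None) -> Tensor:
    """Σ_i w_i/(C_i·H_i·W_i) · ‖V_i(G(x)) − V_i(y)‖₂² over extractor blocks,
    averaged over the batch when a batch is given."""
    fg = extractor.extract(gen_image)
    ft = extractor.extract(target_image)
    if w_content is None:
        w_content = [1.0] * len(fg)
    total = None
    for a, b, w in zip(fg, ft, w_content):
        n_batch = a.shape[0]
        n_i = a.shape[1] * a.shape[2] * a.shape[3]
        term = ((a - b) ** 2.0).sum() * (w / (n_i * n_batch))
        total = term if total is None else total + term
    return total


def style_loss(gen_image, target_image, extractor, w_style=None) -> Tensor:
    """Σ_i w_i · ‖Gr(V_i(G(x))) − Gr(V_i(y))‖_F² over extractor blocks;
    Gram matrices are per image, the loss is averaged over the batch."""
    fg = extractor.extract(gen_image)
    ft = extractor.extract(target_image)
    if w_style is None:
        w_style = [1.0] * len(fg)
    total = None
    for a, b, w in zip(fg, ft, w_style):
        n_batch = a.shape[0]
        term = None
        for n in range(n_batch):
            d = gram_matrix(a[n]) - gram_matrix(b[n])
            contrib = (d ** 2.0).sum()
            term = contrib if term is None else term + contrib
        term = term * (w / n_batch)
        total = term if total is None else total + term
    return total


def perceptual_loss(gen_image, target_image, extractor, alpha: float = 1.0,
                    beta: float = 1.0, w_content=None, w_style=None) -> Tensor:
    """α·content + β·style (the weighted sum of the two feature losses)."""
    total = None
    if alpha != 0.0:
        total = alpha * content_loss(gen_image, target_image, extractor,
                                     w_content)
    if beta != 0.0:
        s = beta * style_loss(gen_image, target_image, extractor, w_style)
        total = s if total is None else total + s
    if total is None:
        total = Tensor(np.zeros(()))
    return total


# ---------------------------------------------------------------------------
# configuration and total objective
# ---------------------------------------------------------------------------

@dataclass
class LossWeights:
    lambda_l1: float = 200.0
    lambda_perceptual: float = 0.1
    lambda_gp: float = 10.0
    alpha: float = 1.0
    beta: float = 1.0
    w_content: list | None = None   # None → all ones
    w_style: list | None = None

    def validate(self):
        for name in ("lambda_l1", "lambda_perceptual", "lambda_gp",
                     "alpha", "beta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class LossConfig:
    adversarial: str            # gan | wgan_gp | lsgan
    similarity: str             # l1 | perceptual
    weights: LossWeights = field(default_factory=LossWeights)
    saturating_gan: bool = True

    @property
    def name(self) -> str:
        return f"{self.adversarial}+{self.similarity}"

    @property
    def lambda_sim(self) -> float:
        return (self.weights.lambda_l1 if self.similarity == "l1"
                else self.weights.lambda_perceptual)


LOSS_NAMES = ("gan+l1", "gan+perceptual",
              "wgan_gp+l1", "wgan_gp+perceptual",
              "lsgan+l1", "lsgan+perceptual")

_ALIASES = {"wgan+l1": "wgan_gp+l1", "wgan+perceptual": "wgan_gp+perceptual",
            "wgan-gp+l1": "wgan_gp+l1",
            "wgan-gp+perceptual": "wgan_gp+perceptual"}


def make_loss_config(name: str) -> LossConfig:
    """One of the six adversarial × similarity combinations, with the
    reference weights."""
    canonical = _ALIASES.get(name, name)
    if canonical not in LOSS_NAMES:
        raise ConfigError(
            f"unknown loss combination {name!r}; valid names: "
            + ", ".join(LOSS_NAMES))
    adv, sim = canonical.split("+")
    return LossConfig(adversarial=adv, similarity=sim)


def total_generator_loss(config: LossConfig, adv_term, sim_term) -> Tensor:
    """L_total = L_adv + λ_sim·L_sim with λ_sim chosen by the similarity
    kind (λ_L1 for l1, λ_perceptual for perceptual)."""
    if config.similarity not in ("l1", "perceptual"):
        raise ConfigError(f"unknown similarity {config.similarity!r}")
    if config.adversarial not in ("gan", "wgan_gp", "lsgan"):
        raise ConfigError(f"unknown adversarial {config.adversarial!r}")
    return _t(adv_term) + config.lambda_sim * _t(sim_term)
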