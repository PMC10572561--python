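"""Quantitative evaluation: PSNR, Fréchet distance between feature
distributions (FID), and the axial PSNR profile.

PSNR follows the convention of computing on [−1,1]-normalized data with
peak R = 1 (``r=2.0`` gives the conventional full-dynamic-range value for
external comparison).  Identical images have infinite PSNR; this is reported
as a documented cap of 99 dB.

FID fits a Gaussian to encoded feature vectors of each image set and
returns ‖μ_d−μ_g‖² + Tr(C_d + C_g − 2(C_d·C_g)^{1/2}).  The matrix square
root is taken by eigendecomposition of the symmetrized product
C_d^{1/2}·C_g·C_d^{1/2}, clipping small negative eigenvalues.  The encoder
is pluggable and its identity is recorded in every report, because FID
values are only comparable within one encoder choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import ConvFeatureEncoder

__all__ = ["PSNR_CAP_DB", "psnr", "FeatureMoments", "feature_moments",
           "fid_from_moments", "fid", "axial_psnr_profile", "EvalReport"]

PSNR_CAP_DB = 99.0


def psnr(x, y, r: float = 1.0) -> float:
    """10·log10(R²/MSE) in dB; MSE = 0 returns the 99 dB cap."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(r * r / mse))


@dataclass
class FeatureMoments:
    """Gaussian fit to a set of encoded feature vectors."""

    mu: np.ndarray
    C: np.ndarray
    n: int


def feature_moments(images, encoder=None) -> FeatureMoments:
    """Sample mean and covariance of encoded features, one vector per image."""
    encoder = encoder or ConvFeatureEncoder()
    feats = np.stack([encoder.encode(im) for im in images])
    if feats.shape[0] < 2:
        raise ConfigError("need at least 2 images for feature moments")
    mu = feats.mean(axis=0)
    C = np.cov(feats, rowvar=False)
    C = np.atleast_2d(C)
    return FeatureMoments(mu=mu, C=C, n=feats.shape[0])


def _psd_sqrt(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD square root with small-negative eigenvalue clipping."""
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    if vals.min() < -max(tol, tol * abs(vals.max())) - 1e-6:
        import warnings
        warnings.warn(f"matrix has significantly negative eigenvalue "
                      f"{vals.min():.3e}; FID may be inaccurate")
    # clip negatives and drop numerically-zero eigenvalues (rank-deficient
    # sample covariances): sqrt of a 1e-15 residual is a 3e-8 error
    floor = max(vals.max(), 0.0) * 1e-12
    vals = np.where(vals < floor, 0.0, vals)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid_from_moments(m_d: FeatureMoments, m_g: FeatureMoments) -> float:
    """Fréchet distance between two Gaussians given their moments."""
    if m_d.mu.shape != m_g.mu.shape:
        raise ConfigError("feature dimensions do not match")
    diff = m_d.mu - m_g.mu
    s_d = _psd_sqrt(m_d.C)
    covmean_sq = _psd_sqrt(s_d @ m_g.C @ s_d)   # = (C_d C_g)^{1/2} spectrum
    val = float(diff @ diff + np.trace(m_d.C) + np.trace(m_g.C)
                - 2.0 * np.trace(covmean_sq))
    return max(val, 0.0) if val > -1e-8 else val


def fid(real_images, gen_images, encoder=None) -> float:
    """FID between two image sets under the given encoder."""
    encoder = encoder or ConvFeatureEncoder()
    return fid_from_moments(feature_moments(real_images, encoder),
                            feature_moments(gen_images, encoder))


@dataclass
class EvalReport:
    """Evaluation summary for one generated stack (or pooled test set)."""

    fid: float | None
    psnr_per_slice: list
    baseline_psnr_per_slice: list
    axial_profile: pd.DataFrame | None = None
    encoder_identity: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fid": self.fid,
            "encoder_identity": self.encoder_identity,
            "median_psnr_generated": float(np.median(self.psnr_per_slice))
            if self.psnr_per_slice else None,
            "median_psnr_baseline": float(
                np.median(self.baseline_psnr_per_slice))
            if self.baseline_psnr_per_slice else None,
            **self.extras,
        }


def axial_psnr_profile(early_stack, gen_stack, gt_stack,
                       r: float = 1.0) -> pd.DataFrame:
    """Per-slice PSNR of the generated and the untranslated early stack
    against the delayed ground truth.

    All three stacks must be aligned and on the same intensity scale
    (normalized [−1,1] for the R=1 convention).  Columns: ``slice_index``,
    ``psnr_gen``, ``psnr_early``, ``improvement_db`` (difference) and
    ``improvement_ratio``.
    """
    e, g, t = (np.asarray(s.voxels if hasattr(s, "voxels") else s,
                          dtype=float)
               for s in (early_stack, gen_stack, gt_stack))
    if not (e.shape == g.shape == t.shape):
        raise ConfigError("stacks are misaligned: "
                          f"{e.shape}, {g.shape}, {t.shape}")
    rows = []
    for i in range(e.shape[0]):
        p_gen = psnr(g[i], t[i], r=r)
        p_early = psnr(e[i], t[i], r=r)
        rows.append({"slice_index": i, "psnr_gen": p_gen,
                     "psnr_early": p_early,
                     "improvement_db": p_gen - p_early,
                     "improvement_ratio": p_gen / p_early
                     if p_early != 0 else np.inf})
    return pd.DataFrame(rows)
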