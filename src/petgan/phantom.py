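"""Kinetic digital phantom: paired early/delayed tracer-activity stacks.

The phantom stands in for whole-body FDG-PET acquisitions: a stack of 2-D
axial slices in which each organ is an elliptical region whose activity
follows a time–activity curve (TAC) modeled as a linear combination of
exponential basis terms, A(t) = Σ_k A_k·exp(−k_k·t).  Rising curves such as
bladder filling are expressed in the same basis, A·(1−e^{−kt}) = A − A·e^{−kt}.

Ground truth is exact: with noise disabled, every voxel inside an organ
carries exactly its TAC value at the requested time, so downstream SUV and
PSNR readouts can be verified against the programmed kinetics.

Conventions: voxel indices are 0-based, axis order is (slice, row, col),
slice 0 is the top of the head.  Organ masks use voxel-center containment;
when organs overlap, the organ listed later in the spec wins (painted on
top).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .io import ImageStack

__all__ = ["OrganSpec", "PhantomSpec", "tac_value", "render_stack",
           "simulate_pair", "apply_degradation", "default_phantom_spec",
           "BACKGROUND_LABEL"]

BACKGROUND_LABEL = 0


@dataclass
class OrganSpec:
    """One elliptical organ with its kinetics.

    ``tac`` is a list of (amplitude in SUV, rate constant in 1/min) pairs;
    the activity at time t minutes is the sum of A·exp(−k·t) over the pairs.
    """

    name: str
    center: tuple          # (row, col) voxel coordinates of ellipse center
    semi_axes: tuple       # (row, col) semi-axes in voxels, > 0
    slice_range: tuple     # [start, stop) slice indices
    tac: list              # [(A_k, k_k), ...]
    noise_scale: float = 1.0
    tac_jitter_scale: float = 1.0   # multiplies inter-subject TAC jitter

    def validate(self, n_slices: int, shape: tuple) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ConfigError(f"organ {self.name!r}: semi-axes must be > 0")
        s0, s1 = self.slice_range
        if not (0 <= s0 < s1 <= n_slices):
            raise ConfigError(
                f"organ {self.name!r}: slice range {self.slice_range} "
                f"outside stack of {n_slices} slices")
        if not self.tac:
            raise ConfigError(f"organ {self.name!r}: empty TAC")
        # A(t) >= 0 for t >= 0, checked on a dense grid plus the t→∞ limit
        t = np.linspace(0.0, 300.0, 601)
        if np.any(_tac_eval(self.tac, t) < -1e-9):
            raise ConfigError(f"organ {self.name!r}: TAC goes negative")
        if sum(a for a, k in self.tac if k == 0) < -1e-12:
            raise ConfigError(f"organ {self.name!r}: negative TAC at t→∞")


@dataclass
class PhantomSpec:
    """Full phantom description; identical (spec, seed) renders bit-identically."""

    n_slices: int = 389
    slice_shape: tuple = (128, 128)
    organs: list = field(default_factory=list)
    background_activity: float = 0.1
    psf_sigma: float = 0.0          # in-plane scanner PSF, voxels; 0 → exact
    poisson_scale: float = 0.0      # expected counts per SUV; 0 → no Poisson
    gaussian_sigma: float = 0.0     # additive Gaussian noise, SUV
    degradation: dict | None = None  # {"kind": none|blur|streak, ...}
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1 or min(self.slice_shape) < 1:
            raise ConfigError("phantom dimensions must be positive")
        if self.background_activity < 0:
            raise ConfigError("background activity must be >= 0")
        for o in self.organs:
            o.validate(self.n_slices, self.slice_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["organs"] = [asdict(o) for o in self.organs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        organs = [OrganSpec(**{**o,
                               "center": tuple(o["center"]),
                               "semi_axes": tuple(o["semi_axes"]),
                               "slice_range": tuple(o["slice_range"]),
                               "tac": [tuple(t) for t in o["tac"]]})
                  for o in d.pop("organs", [])]
        d["slice_shape"] = tuple(d.get("slice_shape", (128, 128)))
        return cls(organs=organs, **d)


def _tac_eval(terms, t):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for a, k in terms:
        out = out + a * np.exp(-k * t)
    return out


def tac_value(organ: OrganSpec, t: float) -> float:
    """Activity (SUV) of an organ at ``t`` minutes post-injection."""
    if t < 0:
        raise ConfigError(f"time must be >= 0, got {t}")
    return float(_tac_eval(organ.tac, t))


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) / semi_axes[0]) ** 2
            + ((cc - center[1]) / semi_axes[1]) ** 2) <= 1.0


def label_map_for(spec: PhantomSpec) -> np.ndarray:
    """Integer labels per voxel: 0 = background, i+1 = ``spec.organs[i]``.

    Later organs override earlier ones where they overlap.
    """
    lab = np.zeros((spec.n_slices, *spec.slice_shape), dtype=np.int16)
    for i, org in enumerate(spec.organs):
        m = _ellipse_mask(spec.slice_shape, org.center, org.semi_axes)
        s0, s1 = org.slice_range
        lab[s0:s1][:, m] = i + 1
    return lab


def render_stack(spec: PhantomSpec, t: float, rng=None,
                 subject_id: str = "phantom"):
    """Render the activity stack at ``t`` minutes → (ImageStack, label_map).

    Without noise, organ voxels equal their TAC value exactly and background
    voxels equal ``background_activity``.
    """
    spec.validate()
    if t < 0:
        raise ConfigError(f"time must be >= 0, got {t}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lab = label_map_for(spec)
    mean = np.full(lab.shape, spec.background_activity, dtype=np.float64)
    noise_scale = np.ones(lab.shape, dtype=np.float64)
    for i, org in enumerate(spec.organs):
        sel = lab == i + 1
        mean[sel] = tac_value(org, t)
        noise_scale[sel] = org.noise_scale
    if spec.psf_sigma > 0:
        # emulate finite scanner resolution / partial volume: in-plane
        # Gaussian PSF on the activity distribution, before counting noise
        mean = ndimage.gaussian_filter(
            mean, sigma=(0.0, spec.psf_sigma, spec.psf_sigma),
            mode="nearest")
    vox = mean
    if spec.poisson_scale > 0:
        counts = rng.poisson(np.clip(mean, 0, None) * spec.poisson_scale)
        vox = counts / spec.poisson_scale
    if spec.gaussian_sigma > 0:
        vox = vox + rng.normal(0.0, spec.gaussian_sigma * noise_scale,
                               size=vox.shape)
    stack = ImageStack(voxels=vox.astype(np.float64),
                       spacing=(4.0, 4.0, 4.0), subject_id=subject_id,
                       time_post_injection=float(t))
    if spec.degradation is not None:
        stack = apply_degradation(stack, spec.degradation, rng=rng)
    return stack, lab


def simulate_pair(spec: PhantomSpec, t_early: float, t_late: float,
                  rng=None, subject_id: str = "phantom"):
    """Paired early/delayed stacks over the same geometry → (early, late, labels)."""
    if not 0 <= t_early < t_late:
        raise ConfigError(
            f"need 0 <= t_early < t_late, got ({t_early}, {t_late})")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    early, lab = render_stack(spec, t_early, rng=rng, subject_id=subject_id)
    late, _ = render_stack(spec, t_late, rng=rng, subject_id=subject_id)
    return early, late, lab


def apply_degradation(stack: ImageStack, degradation: dict | None,
                      rng=None) -> ImageStack:
    """Stylized reconstruction artifacts applied slice-wise.

    ``blur`` is Gaussian smoothing (activity-conserving to within 1%);
    ``streak`` adds a correlated line pattern of bounded amplitude, a crude
    emulation of filtered-back-projection streaks.  These are image-domain
    degradations, not physical reconstructions.
    """
    if degradation is None or degradation.get("kind", "none") == "none":
        return stack
    kind = degradation["kind"]
    vox = stack.voxels
    if kind == "blur":
        sigma = float(degradation.get("sigma", 1.0))
        out = ndimage.gaussian_filter(vox, sigma=(0.0, sigma, sigma),
                                      mode="reflect")
    elif kind == "streak":
        amplitude = float(degradation.get("amplitude", 0.2))
        n_angles = int(degradation.get("n_angles", 8))
        if rng is None:
            rng = np.random.default_rng(0)
        h, w = vox.shape[1:]
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pattern = np.zeros((h, w))
        for _ in range(n_angles):
            theta = rng.uniform(0, np.pi)
            period = rng.uniform(4.0, 16.0)
            phase = rng.uniform(0, 2 * np.pi)
            u = rr * np.cos(theta) + cc * np.sin(theta)
            pattern += np.sin(2 * np.pi * u / period + phase)
        peak = np.abs(pattern).max()
        if peak > 0:
            pattern *= amplitude / peak
        out = vox + pattern[None, :, :]
    else:
        raise ConfigError(f"unknown degradation kind {kind!r}; "
                          "expected none, blur or streak")
    return ImageStack(voxels=out, spacing=stack.spacing,
                      subject_id=stack.subject_id,
                      time_post_injection=stack.time_post_injection)


def vary_spec(spec: PhantomSpec, seed: int, tac_jitter: float = 0.05,
              geom_jitter: float = 0.03) -> PhantomSpec:
    """A per-subject variation of a base phantom.

    Organ TAC amplitudes are scaled by one lognormal-ish factor per organ
    (preserving curve shape and non-negativity) and ellipse centers/axes are
    perturbed by a few percent, emulating inter-subject anatomy and kinetics.
    Deterministic in (spec, seed).
    """
    rng = np.random.default_rng(seed)
    organs = []
    for org in spec.organs:
        scale = float(np.exp(rng.normal(
            0.0, tac_jitter * org.tac_jitter_scale)))
        nr, nc = spec.slice_shape
        dc = rng.normal(0.0, geom_jitter, size=2) * np.array([nr, nc])
        da = np.exp(rng.normal(0.0, geom_jitter, size=2))
        s0, s1 = org.slice_range
        organs.append(OrganSpec(
            name=org.name,
            center=(org.center[0] + dc[0], org.center[1] + dc[1]),
            semi_axes=(org.semi_axes[0] * da[0], org.semi_axes[1] * da[1]),
            slice_range=(s0, s1),
            tac=[(a * scale, k) for a, k in org.tac],
            noise_scale=org.noise_scale,
            tac_jitter_scale=org.tac_jitter_scale))
    out = PhantomSpec(n_slices=spec.n_slices, slice_shape=spec.slice_shape,
                      organs=organs,
                      background_activity=spec.background_activity,
                      psf_sigma=spec.psf_sigma,
                      poisson_scale=spec.poisson_scale,
                      gaussian_sigma=spec.gaussian_sigma,
                      degradation=spec.degradation, seed=int(seed))
    out.validate()
    return out


def default_phantom_spec(n_slices: int = 389, slice_shape=(128, 128),
                         seed: int = 0, psf_sigma: float = 0.0,
                         poisson_scale: float = 0.0,
                         gaussian_sigma: float = 0.0,
                         degradation: dict | None = None) -> PhantomSpec:
    """Seven-organ whole-body phantom (muscle, brain, heart, liver, spleen,
    kidney, bladder) with illustrative FDG-like kinetics.

    Most organs decay slowly or plateau between the early and delayed scans;
    the bladder fills, i.e. follows a strongly rising A·(1−e^{−kt}) curve,
    which is the hardest region for early→delayed translation.  Organ
    placement is expressed as fractions of the stack so any resolution works.
    """
    ns, (nr, nc) = n_slices, slice_shape

    def sl(a, b):
        return (int(round(a * ns)), max(int(round(a * ns)) + 1,
                                        int(round(b * ns))))

    def pt(r, c):
        return (r * (nr - 1), c * (nc - 1))

    def ax(r, c):
        return (max(1.5, r * nr), max(1.5, c * nc))

    organs = [
        # torso muscle first: lowest priority, everything else painted on top.
        # Soft tissue / blood pool clears markedly between early and delayed
        # scans, so mid-body slices genuinely change appearance.
        OrganSpec("muscle", pt(0.5, 0.5), ax(0.34, 0.38), sl(0.13, 1.0),
                  tac=[(0.4, 0.0), (0.7, 0.025)]),          # 0.89 → 0.59
        # scalp/facial soft tissue around the brain: same tissue class as
        # muscle, so head slices carry torso-like context
        OrganSpec("muscle", pt(0.5, 0.5), ax(0.31, 0.33), sl(0.0, 0.13),
                  tac=[(0.4, 0.0), (0.7, 0.025)]),
        # brain uptake plateaus by the early scan; modest residual rise
        OrganSpec("brain", pt(0.5, 0.5), ax(0.26, 0.28), sl(0.0, 0.11),
                  tac=[(6.0, 0.0), (-2.0, 0.06)]),          # rises 5.1 → 5.9
        OrganSpec("heart", pt(0.45, 0.38), ax(0.09, 0.09), sl(0.24, 0.33),
                  tac=[(1.8, 0.0), (2.2, 0.02)]),           # decays 3.5 → 2.6
        OrganSpec("liver", pt(0.48, 0.62), ax(0.16, 0.19), sl(0.36, 0.52),
                  tac=[(1.2, 0.0), (1.4, 0.025)]),          # decays 2.2 → 1.6
        OrganSpec("spleen", pt(0.52, 0.28), ax(0.07, 0.07), sl(0.40, 0.50),
                  tac=[(0.9, 0.0), (0.9, 0.03)]),
        OrganSpec("kidney", pt(0.62, 0.40), ax(0.07, 0.07), sl(0.50, 0.60),
                  tac=[(1.0, 0.0), (2.0, 0.05)]),           # fast washout
        # bladder fills strongly and, unlike every other organ, varies a lot
        # between subjects (void timing, hydration): large jitter scale
        OrganSpec("bladder", pt(0.55, 0.5), ax(0.09, 0.09), sl(0.84, 0.93),
                  tac=[(12.0, 0.0), (-12.0, 0.03)],         # fills 0 → 12
                  tac_jitter_scale=8.0),
    ]
    return PhantomSpec(n_slices=ns, slice_shape=tuple(slice_shape),
                       organs=organs, background_activity=0.1,
                       psf_sigma=psf_sigma, poisson_scale=poisson_scale,
                       gaussian_sigma=gaussian_sigma,
                       degradation=degradation, seed=seed)
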