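# Methods

## Problem and model

`petgan` learns a mapping from an early-uptake PET slice to its
delayed-uptake appearance, so that a single early scan can stand in for a
later acquisition.  Training data are spatially corresponding axial slice
pairs (early, delayed) from the same subject; the model is a conditional
adversarial translator in the pix2pix family:

- **Generator** G: a U-Net encoder–decoder over 4×4 stride-2 convolutions
  (no pooling), leaky-rectifier activations on the way down, rectifiers on
  the way up, mirrored skip connections, and a saturating output so every
  generated slice lies in [−1, 1].
- **Discriminator** D: a conditional PatchGAN.  It receives the early slice
  concatenated channel-wise with a real or generated delayed slice and
  emits a 2-D grid of raw patch scores; with the default 3 stride-2 layers
  each score covers a 70×70-pixel patch.

Three adversarial objectives are implemented (cross-entropy GAN; Wasserstein
with gradient penalty, `x̂ = εx + (1−ε)x̃`, ε∼U(0,1) per sample; least
squares), crossed with two similarity terms (L1; perceptual = α·content +
β·style with Gram-matrix style representations), giving the six
combinations.  The generator minimizes

    L_total = L_adv(G, D) + λ_sim · L_sim(G)

with λ_L1 = 200, λ_perceptual = 0.1, λ_gp = 10, α = β = 1 and unit
per-block feature weights.  Both networks use Adam (lr₀ = 2·10⁻⁴, β₁ = 0.5,
β₂ = 0.999) with the learning rate decayed to lr₀·0.98^epoch.  Each step
updates D first (generator output detached), then G with D fixed.

### Numerical substrate

The networks run on a small reverse-mode autodiff engine written on numpy
(`petgan.engine`).  Backward functions are themselves built from the
engine's primitives, so gradients are differentiable again; the WGAN
gradient penalty — a loss on ∇ₓ̂D(x̂) — uses this directly, and
`engine.grad` computes that inner gradient without polluting parameter
gradients.  For a linear critic the penalty is exact:
λ(‖w‖₂−1)², with the analytic parameter gradient recovered to machine
precision (this is a unit test).  All network arithmetic is float32;
python-scalar constants adopt the tensor dtype so graphs are never silently
promoted, which keeps checkpoint/resume bit-reproducible.

### Design choices in the architecture

- **Conditional D**: the discriminator always sees the early slice alongside
  the candidate; conditioning is the standard for paired translation.
- **Residual generator (option)**: with `GeneratorSpec.residual=True` the
  network predicts the uptake *change*, which is added to the input and
  clamped to [−1, 1]; the final layer starts at zero so the untrained
  generator is the identity map.  Same-modality uptake-time translation has
  a small style difference by construction, and learning the change rather
  than re-synthesizing the whole image reaches high fidelity in far fewer
  steps.  The plain tanh U-Net is the default of the spec'd architecture;
  the residual form is what the bundled experiment pipeline uses.
- **Normalization layers**: batch norm is the `networks` default, instance
  norm selectable; the experiment pipeline defaults to instance norm (no
  cross-sample coupling, no train/eval statistics gap).  A WGAN-GP critic is
  always built without normalization: the per-sample gradient penalty is
  ill-defined under cross-sample batch statistics.
- **Vanilla GAN generator** uses the saturating objective by default (the
  literal minimax form); a non-saturating switch exists.

### Feature extractor and FID encoder

The perceptual loss and FID are defined over features of a convolutional
encoder.  The reference construction uses large pretrained classifiers;
this package ships a small fixed-seed random convolutional extractor
instead, so results are self-contained and bit-reproducible offline.  Its
weights use He-style variance scaling with a gain of 2 per block, which
puts feature-space distances on the magnitude scale of deep pretrained
features — without this, λ_perceptual = 0.1 would make the similarity term
negligible against the adversarial term.  Random convolutional features
preserve distributional geometry well enough for a relative metric, but FID
values are only comparable within one encoder choice, so every report
records the encoder identity string.  Both the extractor and the FID
encoder are pluggable interfaces.

## The kinetic digital phantom

The phantom emulates paired whole-body FDG-PET stacks.  Each organ is an
elliptical region per axial slice whose activity follows a time–activity
curve that is a linear combination of exponential basis terms
A(t) = Σₖ Aₖ·exp(−kₖ·t); rising curves (bladder filling) are expressed in
the same basis as A·(1−e^(−kt)).  The default seven-organ layout (muscle —
including a scalp/facial soft-tissue region so head slices carry body-like
context — brain, heart, liver, spleen, kidney, bladder) uses illustrative
FDG-like kinetics in SUV units between the default time points of 14 and
52 minutes post-injection:

| organ   | t=14 min | t=52 min | behaviour |
|---------|---------:|---------:|-----------|
| muscle  | 0.89     | 0.59     | soft-tissue clearance |
| brain   | 5.14     | 5.91     | plateau with residual rise |
| heart   | 3.46     | 2.58     | washout |
| liver   | 2.19     | 1.58     | washout |
| spleen  | 1.49     | 1.09     | washout |
| kidney  | 1.99     | 1.15     | fast washout |
| bladder | 4.12     | 9.48     | strong filling |

Per-subject variation (`vary_spec`) scales each organ's TAC by one
lognormal factor (σ = 5%) and jitters ellipse geometry by a few percent.
The bladder's jitter is 8× larger (σ ≈ 40%): bladder content at a fixed
uptake time varies enormously across subjects (void timing, hydration),
and this variability — not the mean trend — is what makes the bladder
untranslatable from an early scan.  This is deliberately the hardest region
of the phantom.

Realism layers, all optional and off by default so that noiseless renders
equal the programmed TAC values voxel-exactly:

- **PSF** (`psf_sigma`, voxels): in-plane Gaussian smoothing of the
  activity distribution before noise, emulating finite scanner resolution /
  partial volume.  The experiment default is 0.8 voxel.
- **Counting noise** (`poisson_scale`, expected counts per SUV): voxel
  values are Poisson draws divided by the scale.  The experiment default of
  200 gives organ-level relative noise of a few percent, appropriate for
  the coarse (≈16 mm at 32×32) voxels of the desk-scale study.
- **Additive Gaussian noise** and stylized reconstruction **degradations**
  (Gaussian blur; bounded correlated streak patterns standing in for
  filtered-back-projection artifacts).  These are image-domain stylizations,
  not physical reconstructions.

What the phantom does *not* emulate: attenuation/scatter, sinogram-level
physics, anatomical texture within organs, respiratory motion, or
inter-organ spill-over beyond the isotropic PSF.  Passing the end-to-end
tests therefore shows that the training loop, losses and evaluation behave
correctly on data with known kinetics — not that clinical image quality is
reached on real scans.

## Normalization

Files always store SUV; normalization to [−1, 1] is an in-memory affine
map x ↦ 2(x−lo)/(hi−lo)−1 whose parameters invert it exactly, so SUV
readout after translation is exact.  The experiment pipeline computes one
range over the union of the *training* split's early and delayed stacks
and applies it to all splits: a shared scale keeps the early→delayed
intensity change learnable and makes the mapping consistent across
subjects (with per-subject ranges, the scale is set by the subject's
bladder maximum, and slices that do not show the bladder become
ambiguous).  Held-out subjects never influence the range; test values
outside it simply map outside [−1, 1].

## Evaluation

- **PSNR** = 10·log₁₀(R²/MSE) on normalized data with R = 1 (a
  `r=2` flag gives the conventional full-range value).  Identical images
  are reported at a 99 dB cap.
- **FID** = ‖μ_d−μ_g‖² + Tr(C_d + C_g − 2(C_d·C_g)^{1/2}) over encoded
  feature moments, pooled across test subjects.  The matrix root is taken
  by eigendecomposition of C_d^{1/2}·C_g·C_d^{1/2} with negative and
  numerically-zero eigenvalues (relative threshold 10⁻¹²) clipped — sample
  covariances from few images are rank-deficient and the root of a 10⁻¹⁵
  residual eigenvalue would otherwise contribute ~10⁻⁸ each.
- **Axial profile**: per-slice PSNR of the generated stack and of the
  untranslated early stack against the delayed ground truth, plus their
  difference (dB) and ratio.  The difference is the primary readout; the
  ratio is also reported since the reference figure is expressed that way.
- **SUV_mean**: arithmetic mean over an ROI mask (voxel-center membership,
  no partial-volume weighting) on denormalized stacks, with per-organ
  absolute errors |SUV_gen − SUV_gt|.  ROIs come from the phantom label
  map; labels sharing a tissue name are merged.

## The scaled-down study

The bundled study (also what `scripts/acceptance.py` runs) uses 13
subjects × 20 slices of 32×32 — 10 training subjects (200 slice pairs),
1 validation, 2 test — t_early = 14 min, t_late = 52 min, PSF 0.8 voxel,
poisson_scale 200, LSGAN adversarial loss with L1 or perceptual
similarity, 18 epochs at the reference optimizer settings, and a reduced
network (3-level residual U-Net, 16 base channels; 2-layer PatchGAN).
These sizes were chosen so the full study trains in about a minute on one
CPU core while keeping ≥10 slices per organ region in training.

Expected behaviour, mirroring the reference findings qualitatively:
median held-out PSNR of the generated stack exceeds the untranslated-early
baseline; the improvement is strong on mid-body slices (washout organs),
moderate on head slices, and smallest on the bladder slices; organ-wise
SUV_mean errors are small for muscle/heart/liver/spleen (≲0.1 SUV here),
larger for kidney and brain, and large for the bladder (≳1.5 SUV), whose
filling is dominated by inter-subject variability that an early scan
cannot reveal.

A note on split arithmetic: at the reference cohort size (18 subjects,
12/4/2 at 389 slices each) the subject-level split yields 4668/1556/778
slices.  The source text prints a test count of 776 alongside "2 × 389",
which is arithmetically inconsistent; this package uses the exact
arithmetic and makes no attempt to guess which figure was intended.

## Degenerate inputs and tie-breaks

- Constant stacks cannot be auto-normalized (error); explicit params work.
- Overlapping organs resolve to the organ listed later in the spec.
- TACs are validated non-negative on a dense grid over [0, 300] min and in
  the t→∞ limit.
- Empty organ lists render pure background; empty score batches,
  zero-size masks, and mismatched shapes raise configuration errors.
- Training aborts with a divergence error (CLI exit code 4) on any
  non-finite loss, naming the epoch and step.

## Known limitations

- The phantom's geometric simplicity means translation here is far easier
  than on clinical data; absolute PSNR/FID values are not comparable to
  values computed with deep pretrained encoders on real scans.
- FID with the bundled encoder is a relative, encoder-specific number.
- The 2-D slice-wise treatment ignores axial correlations (a 3-D variant
  is out of scope).
- Perceptual-loss block weights and extractor depth are conventions, not
  fitted quantities.
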