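# Methods

## The model

`braincam` predicts a scalar anthropometric trait (BMI, kg/m²) from a
T1-weighted brain volume registered to a common space, optionally fused
with two scalar covariates (age in years, sex coded 0/1), and produces
3D localization maps of the regions driving each prediction.

### Architecture

The regression network is a cascade of 8 blocks of **spatially separable
3D convolutions**: every N×N×N convolution is factored into three
asymmetric stages N×1×1 → 1×N×1 → 1×1×N, each with its own bias, stride
1 and SAME zero padding. Kernel extent is 5 in the first block and 3
afterwards; the channel schedule is 1→8→16→16→32→32→64→64→128 (filter
count doubled entering blocks 2, 4, 6, 8). Each block ends with one
batch-normalization stage over its output channels followed by ReLU;
blocks 2, 4 and 6 are followed by 3×3×3 max pooling with stride 2 and
SAME boundary handling. Global average pooling (GAP) reduces the last
block's 128 feature maps to one scalar each; the covariates are
concatenated (130 values), and a 128-unit fully connected hidden layer
with ReLU and dropout (rate 0.4 during training) feeds a single linear
output unit.

Parameter accounting, per block with extent N and channels c_in → c_out:

    weights   N·c_in·c_out + 2·N·c_out²
    biases    3·c_out
    BN        2·c_out trainable (scale, shift) + 2·c_out running stats

| block | N | channels | weights | biases | BN train | BN stats |
|---|---|---|---|---|---|---|
| 1 | 5 | 1→8    | 680     | 24  | 16  | 16  |
| 2 | 3 | 8→16   | 1 920   | 48  | 32  | 32  |
| 3 | 3 | 16→16  | 2 304   | 48  | 32  | 32  |
| 4 | 3 | 16→32  | 7 680   | 96  | 64  | 64  |
| 5 | 3 | 32→32  | 9 216   | 96  | 64  | 64  |
| 6 | 3 | 32→64  | 30 720  | 192 | 128 | 128 |
| 7 | 3 | 64→64  | 36 864  | 192 | 128 | 128 |
| 8 | 3 | 64→128 | 122 880 | 384 | 256 | 256 |

Trainable block total 214,064; hidden stage 130·128+128 = 16,768; output
128+1 = 129; so 230,961 trainable parameters plus 2×360 = 720 running
statistics = 231,681 overall. These two integers are a strong structural
checksum: they pin down the channel schedule, the presence of biases in
all three asymmetric stages, and one batch-normalization stage per block
(not per stage) — a bias-free build falls 1,080 parameters short, and
per-stage normalization triples the running statistics.

Design points the parameter counts alone cannot pin down, resolved here:

- **No nonlinearity between the three asymmetric stages** within a
  block; the cascade acts as one factored linear convolution. Parameter
  counts cannot discriminate this, so the simpler reading is used.
- **Pooling placement** after blocks 2, 4, 6; the final block feeds GAP
  directly. Pooling carries no parameters, so the counts are unaffected.
- **SAME pooling** (output length = ceil(n/2)), matching the convention
  of the convolutions.
- Convolution biases initialize to 0; the 0.01 initialization applies to
  the fully connected biases only. Weights are Xavier/Glorot uniform;
  batch-norm scale/shift start at 1/0 and running mean/variance at 0/1.

Because GAP absorbs spatial extent, the same configuration runs on any
input shape that survives three pooling stages; the parameter count is
shape-independent.

### Training

Mean squared error loss, Adam (default learning rate 5e-4, β₁ 0.9,
β₂ 0.999, ε 1e-8), batch size 8, shuffling each epoch, 50 epochs by
default. Validation MAE is computed after every epoch and the parameter
snapshot of the best epoch (earliest on ties) is restored — "snapshot
restore". The last incomplete batch of an epoch is used, not dropped.
Three independent seeded random streams drive data order, dropout masks
and augmentation, so they can be varied independently. Fine-tuning runs
the identical protocol from pretrained weights with rigid augmentation
of every training volume as drawn: rotation up to a bound (default 5°)
about a uniformly chosen grid axis, cubic-spline resampled, plus an
integer translation up to a bound (default 10 voxels) per axis, zero
fill; validation volumes are never augmented.

Covariates are fed raw by default. An optional switch standardizes them
with training-set statistics (stored in the checkpoint); this matters
when raw covariate scales (age ≈ 45–80) would otherwise dwarf the
O(1) pooled features early in training.

### Localization (regression Grad-CAM)

For a prediction y, the gradient ∂y/∂A^n with respect to each feature
map A^n of the last block (post batch-norm and ReLU — the conventional
capture point) is averaged over its Z spatial units into an importance
weight α_n, and the signed map L = Σ_n α_n A^n is formed. No ReLU is
applied to L: with a single regression output, voxels lowering the
prediction are as meaningful as voxels raising it. L is upsampled to
input resolution by cubic spline, standardized to zero mean/unit
variance over the grid (no brain mask by default; an optional mask can
restrict the statistics), averaged voxelwise across subjects,
re-standardized, and thresholded at |Z| > 2 to yield a cohort mask.
Per-subject maps are computed one at a time in evaluation mode, so
batch-norm running statistics make them batch-independent.

**Upsampling registration.** SAME pooling with window 3 and stride 2
places the receptive-field center of feature cell c at input index
2c+1 per level when the level's length is even (2c when odd); composing
the three pooling stages gives, e.g., centers 8c+7 on even axes and
8c+2 on an axis of length 91. The pipeline's `subject_map` upsamples
with this registration (`receptive_field_geometry` +
`map_coordinates`); a corner-aligned zoom — which misplaces cells by up
to half a cell — is available in the standalone `upsample_map` for
compatibility with the simplest resize convention.

## The phantom generator

Synthetic cohorts provide ground truth for both prediction and
localization. Each volume (default 32×40×32 voxels at a nominal 2 mm)
is an ellipsoidal head (semi-axes 14, 18, 14 voxels; base intensity 10)
containing spherical signal regions whose intensity couples linearly to
the subject's target, plus covariate effects and i.i.d. Gaussian noise:

    V = base·E + Σ_r β_r·(t − t̄)·S_r + γ_age·(age − midage)·E
        + γ_sex·sex·S_sex + N(0, σ²)

Defaults: two spheres — deep (center (12,16,16), radius 4) and lateral
(center (22,26,16), radius 3) — with β = 1.0 each; the lateral sphere
doubles as the sex region (γ_sex = 1.0); γ_age = 0.05 per year;
σ = 2.0. Targets are Normal(26.15, 4.72²) truncated positive — a
realistic adult female BMI distribution; ages Uniform(45, 80); sex
Bernoulli(0.5). Per-voxel contrast-to-noise inside a sphere is
β·SD_t/σ ≈ 2.4. Coupling to the *centered* target keeps mean image
brightness target-independent, so prediction requires reading the
planted regions. Subject draws are keyed by (seed, subject index):
cohorts are deterministic and order-invariant.

The phantom emulates common-space registration, localized linear
structure–trait coupling, covariate confounding and additive noise. It
does not emulate anatomy, intensity bias fields, scanner/site effects,
nonlinear couplings, or registration error — success here shows the
pipeline recovers planted linear signal, not that it matches any
particular neuroanatomical finding.

### Desk-scale protocol and what it shows

The full acceptance loop (generate → train → evaluate → localize) runs
on one CPU. The documented desk protocol trains the reference
architecture on 240 phantom subjects (160/40/40 split) for 6 epochs
with Adam at learning rate 5e-3, batch 8, dropout 0.4, and
standardized covariates. The raised learning rate compensates for the
tiny number of optimizer steps (20 per epoch versus ~1,700 at
population scale, where 5e-4 is appropriate); 6 epochs suffice for the
held-out Pearson r to exceed 0.9 — r measures whether the net reads
the planted signal and is insensitive to the slower output-scale
calibration, which continues to improve MAE for tens of epochs (MAE
≈ 1.3 kg/m² at 6 epochs, ≈ 0.5 at 30 on seed 0).

### Localization at phantom scale: known limitation

At 32×40×32 the last-block feature grid is 4×5×4 — each cell summarizes
an 8×8×8-voxel receptive-field neighborhood. Two consequences for the
cohort-average map:

1. **Resolution floor.** The |Z|>2 super-level set of a single
   upsampled feature cell is a smooth bump of roughly 2,000 voxels,
   substantially larger than a dilated radius-3–4 sphere (≈ 500–1,400
   voxels). Even a perfectly centered peak therefore yields a modest
   precision-style overlap score (observed ≈ 0.2 at |Z|>2, rising to
   1.0 by |Z|>4.5 — the peak is exactly on the planted region; the
   shoulder is what spills).
2. **Sign cancellation.** Per-subject maps are signed: a region coupled
   to (t − t̄) contributes positively for above-average subjects and
   negatively for below-average ones (the per-subject map value there
   correlates ≈ 0.9 with the target), so the cohort average attenuates
   it. Regions with sign-consistent effects across subjects — here the
   sex-coupled sphere — survive averaging. Cohort-average maps of
   signed regression Grad-CAM should be read as "consistently used
   regions", not as a per-subject effect atlas; averaging |Z| or
   splitting the cohort by target would surface symmetric couplings,
   but is not part of this pipeline.

At the native 91×109×91 scale the feature grid is 12×14×12 (cells ≈
8 mm across ≈ 15 mm of anatomy), so the resolution floor is relatively
less severe.

## Numerical choices

- All training runs in float32; gradient-check and oracle tests build
  float64 networks. The layers' backward passes are verified against
  central finite differences (≤ ~1e-6 relative error per layer in
  float64) and the separable convolution against scipy's 1D correlation.
- Batch normalization: ε = 1e-5, running-stat momentum 0.9 (running ←
  0.9·running + 0.1·batch). Evaluation mode uses running statistics
  exclusively, making predictions batch-composition invariant.
- Adam ε = 1e-8.
- Standardization of a constant map raises a degenerate-map error (the
  cohort-average of mutually cancelling maps likewise); Pearson r on a
  constant vector is reported as 0 with a warning rather than NaN.
- Cohort splitting: validation and test sizes are round(n·fraction);
  the remainder goes to train. Resampling output lengths are
  round(n·factor), matching 182→91 and 218→109 at factor 0.5.
- Ties in the best-validation epoch resolve to the earliest epoch.
- Max pooling SAME padding puts the extra pad on the right (ceil
  semantics); pooled gradients scatter to the argmax element per
  window (first index on exact ties, following argmax convention).

## Known limitations

- No learning-rate schedules, weight decay, early stopping (beyond
  snapshot restore), or distributed training.
- The NumPy engine favors clarity and 1-CPU throughput; it processes
  one batch at a time and is not competitive with GPU frameworks at
  population scale.
- DICOM and 4D images are out of scope; volumes must share a common
  space for cohort-level maps to be meaningful.
- Intensity normalization is intentionally absent by default (volumes
  are used as stored).
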