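# Methods

`ventimap` derives regional lung ventilation maps from a ten-phase,
phase-binned thoracic acquisition (T00 = peak inhale … T50 = peak exhale …
T90) by three routes, and evaluates them against a reference ventilation
image the way functional-lung studies do.  Because clinical 4D-CBCT + SPECT
pairs are not freely available, everything is verifiable on a synthetic
breathing-lung phantom whose ventilation is known in closed form.

## The estimators

**Density change (HU).**  Under the air/tissue mixture model, lung density
(1000 + HU) is proportional to tissue fraction, and regional air-volume
change follows from the HU of corresponding inhale/exhale tissue:

    VI_HU = 1000 (H̃ − HU_T50) / (HU_T50 (1000 + H̃)),

evaluated at every exhale-masked voxel, where H̃ is the mean inhale HU over
the exhale voxel's mapped volume of interest (VOI).  The VOI is discretized
as the set of inhale-grid voxel centers inside the axis-aligned bounding box
of the voxel cell's eight corners mapped through the displacement field,
falling back to trilinear sampling at the mapped center when the box
captures no center (strong local contraction).  This construction converges
to the continuum definition as the grid refines, and is exact on the
phantom, where motion is axial and the expansion field is constant along z.
Voxels with degenerate denominators (exhale HU ≈ 0 from vessels, or mapped
mean ≈ −1000) are zeroed and counted; more than 10% guarded voxels raises
an error, since that signals a broken registration or mask.

**Jacobian (JAC).**  VI_JAC = det(I + ∇u) − 1, the local volume expansion
ratio minus one.  ∇u is computed in physical millimetres, central
differences in the interior and one-sided at boundaries, and the 3×3
determinant is expanded explicitly.  On any displacement affine in the
coordinates the result is exact to rounding — this is the module's
anchor test, alongside an independent cross-check against SimpleITK's
displacement-field Jacobian filter.

**Learned regressor (DL).**  A 2-D U-net maps an axial stack of phase
slices directly to the reference ventilation slice, with no registration:
encoder blocks of two 3×3 convolutions + ReLU (dropout optional) and 2×2
max-pooling with filters doubling per level; a mirrored decoder with 2×2
nearest upsampling, a 3×3 convolution + ReLU, skip concatenation and two
3×3 convolutions + ReLU; a head of one 3×3 convolution + ReLU and a 1×1
convolution (ReLU-constrained nonnegative by default, since the reference
is count-derived).  Input modes: `phases10` (10 channels), `phases2`
(T00 and T50 only), `phases10_adjacent` (2.5D; each phase contributes the
slice and both axial neighbors, 30 channels).  The network engine
(im2col convolutions, pooling, dropout, RMSprop, he-normal initialization,
full backpropagation) is implemented in numpy and is deterministic given
its seeds; gradient correctness is tested against central differences.

Training: MSE over the whole slice (labels zeroed outside the lung;
mask-weighted loss exists but is off by default), RMSprop at 1e-4,
mini-batches of 4, an 80/20 *subject-level* train/validation split,
learning-rate drop ×0.2 after 10 stagnant validation epochs, early stop
after 15, restoration of the minimum-validation-loss weights, and
augmentation applying the same flip/rotation(±10°)/scale(±10%)/shift to
all channels and the label.  Inputs are scaled (HU + 1000)/1000 clipped to
[0, 2]; labels are normalized per subject by the in-mask 90th percentile
(MSE needs commensurate scales; the percentile mirrors the post-processing
convention).  Splitting is always by subject, never by slice, and the
cross-validation harness audits subject ids so no test subject's slices can
reach training or validation.

## Post-processing (all estimators)

(1) multiply by the exhale (T50) lung mask, (2) divide by the 90th
percentile of in-mask values, (3) median-filter with a 9×9×9 box (reflect
padding) over the full grid, (4) re-zero outside the mask.  Normalization
precedes filtering; a test pins this order.  Scale invariance —
postprocess(k·v) = postprocess(v) for k > 0 — holds to machine rounding.
The percentile is computed over in-mask voxels only (a whole-image
percentile would be dominated by the zero background).  Negative values
(possible for the HU method under noise) are retained; tertile segmentation
downstream is rank-based.  On coarse grids the 9-voxel box can span a third
of a small lung; prediction and evaluation functions therefore expose the
filter size, and the desk-scale experiments use 1 (no smoothing).

## Registration

The displacement field lives on the exhale grid and points to inhale
positions, so J ≈ inhale/exhale volume ratio ≥ 1 in ventilated lung and
VI_JAC ≥ 0.  (Read literally, a transformation "projecting inhale to
exhale" would give J ≤ 1 and negative ventilation; the convention here is
the one that makes displayed ventilation maps nonnegative.)

`demons_register` is a classical multiresolution intensity-driven scheme:
Thirion update (residual × fixed-image gradient over |∇F|² + diff²/s²),
Gaussian smoothing of the update (fluid-like, default 1 mm) and of the
accumulated field (diffusion-like, default 2 mm) each iteration,
coarse-to-fine over 3 levels with default iterations (80, 60, 80).
Implementation notes that mattered:

* smoothing sigmas are floored at 0.5/1.0 voxels per level — at a 4×
  downsampled level a 1–2 mm physical sigma is sub-voxel and the update
  field oscillates unregularized;
* residuals below 1e-3 HU are deadbanded — the normalized force would
  amplify numerically-zero residuals in flat regions, breaking the
  fixed==moving fixed point;
* interior sampling is edge-clamped — constant-fill sampling turns
  sub-nanometre boundary displacements into ±1000 HU spurious forces;
* **mass compensation** (default on): the warped inhale intensities are
  multiplied by the current Jacobian before the residual, because breathing
  genuinely changes lung HU ((1000+HU) scales with 1/local volume).
  Without it the ~30 HU brightness-constancy violation biases texture
  alignment by offset/|∇texture| ≈ 5 mm.  A per-level high-pass prefilter
  is available as an alternative.
* early stopping only on a genuine plateau (tiny relative MSE change,
  three consecutive iterations): transient MSE rises during coarse-level
  alignment are not a stopping signal.

On the noiseless phantom this recovers the breathing field to a mean
endpoint error of ~1.0 mm (half a voxel) inside the lungs, is bit-identical
across runs, degrades monotonically with image noise, and is
inverse-consistent to ~1 mm.

## The phantom

A body ellipsoid (+40 HU) holds two lung ellipsoids (exhale −800 HU) and a
midline trachea (−1000 HU) on a 96×96×64 grid at 2 mm.  Breathing is a
dorsoventral-graded uniaxial expansion about an apex plane z0:
u_z = w·a(x,y)·(z − z0) inside the lungs with
a(x,y) = a0 + a1·(y − y_min)/(y_max − y_min), depressed inside Gaussian-edged
defect blobs, cosine-tapered to zero over a 6 mm shell starting one voxel
outside the lungs (the margin keeps finite differences exact at every
in-mask voxel).  The displacement gradient is unit-lower-triangular, so the
Jacobian is exactly 1 + w·a(x,y) — the closed form every estimator is
tested against.  Phase weights follow w(p) = (1 + cos(2πp/10))/2 (smooth,
symmetric; intra-cycle timing is otherwise arbitrary).

Phases are rendered through the exact inverse map
z = z0 + (z′−z0)/(1+w·a), with lung HU satisfying mass conservation
(1000 + HU_phase) = (1000 + HU_exhale)/(1 + w·a) at the material point —
this makes the density-change and Jacobian truths mutually consistent, and
on a texture-free phantom VI_HU = 1000·(J−1)/(−HU_ex) exactly.  A
vascular-like additive density texture (sum of 10 plane waves, wavelengths
8–25 mm, amplitude 40 HU, a fixed function of the exhale material
coordinate advected exactly with the deformation) gives the interior the
local contrast that makes intensity-driven registration well-posed, as
vessels do in real lungs.  Gaussian noise (default sd 15 HU) and a smooth
multiplicative shading field (default amplitude 0.05, per-phase) emulate
cone-beam noise and shading; the subject seed drives only these, never
anatomy or truth.  Default ventilation pattern: a0 = 0.15, a1 = 0.10
(≈1.7× dorsoventral gradient, a normal tidal range), one defect blob;
cohort generation jitters geometry and pattern and draws 1–3 defects per
subject — thoracic-cancer cohorts essentially always show deficits, and a
near-constant true pattern makes voxel-wise rank correlation meaningless as
a validation metric.

The reference ventilation image degrades the truth the way a coarse
emission scan sees it: Gaussian blur (sigma 4 mm ≈ 9 mm FWHM), block
averaging onto a 4× coarser grid (~8 mm), count-like noise (variance ∝
local mean; default scale equivalent to ~100 counts at a typical in-lung
value, ~10% relative), clipped at zero, trilinearly interpolated back.
Blur and coarsening are normalized convolutions weighted by the lung mask,
so boundary values are local in-lung averages rather than being diluted
toward the zero background; real emission references *do* show edge
partial-volume rolloff, which this choice deliberately removes so that
in-lung pattern agreement, not boundary-distance, drives the comparison
metrics.

What the phantom does not emulate: scatter streaks and truncation
artifacts, hysteresis (inhale/exhale path asymmetry), tumors, perfusion,
and real SPECT reconstruction physics.  Passing tests show the estimators
and harness are correct under the stated model; they do not certify
clinical accuracy.

## Evaluation

Masked voxel-wise Spearman correlation (average ranks on ties; constant
input raises rather than silently returning 0).  Tertile functional-lung
segmentation at the 33⅓ and 66⅔ linear-interpolation percentiles of in-mask
values; ties go deterministically to the higher region.  Regional Dice
2|A∩B|/(|A|+|B|) for HFL/MFL/LFL plus their mean; both-empty regions define
DSC = 1 with a warning (cannot occur with valid tertiles).  Independent
random tertile maps give DSC_avg → 1/3, the chance floor.  Method
comparison: one-way ANOVA on per-subject averaged DSC with Tukey HSD
pairwise p-values (scipy's studentized-range implementation); a
null-calibration test checks the F p-value is uniform under exchangeable
groups.  Spearman uses the exhale (T50) lung mask throughout.

## Desk-scale experiment design

Tests and the acceptance script must run on one CPU in minutes, so the
learned-regressor experiments use: a cohort of 8 subjects on a 96×96×32
grid at 2×2×4 mm (2 mm in-plane keeps the boundary shell a small fraction
of the mask; 4 mm slices keep ~20 samples per subject), 6 training / 2
held-out subjects, `phases2` input, U-net depth 3 with 8 base filters at
64×64, dropout 0, augmentation with the shift range scaled to the field of
view (3 px ≈ 5% of 64, the fraction 10 px is of a 192 plane), and up to 150
epochs under the plateau/early-stop schedule (~5 minutes).  The clinical
scale configuration (192×192, depth 4, base 64, dropout 0.2) remains the
`ModelConfig` default.  Dropout 0.2 at 8 base filters floors validation
loss well above the dropout-free optimum — the rate is a capacity-dependent
choice, and the reported drop rate in the training recipe this follows is
the learning-rate factor, not a dropout rate.

The DL cohort is texture-free.  The vascular texture is a function of the
material coordinate and breathing motion is axial, so between phases the
texture moves *through* the axial slice planes; a 2-D slice model cannot
de-alias it, and the measured information ceiling of even an analytic
density-ratio estimator drops to rs ≈ 0.1 with texture versus ≈ 0.7
without.  Registration experiments, which need the texture, keep it.

## Known limitations

* **Jacobian of an estimated registration is noise-dominated at this
  signal contrast.**  The phantom's ventilation signal has sd ≈ 0.03
  (dimensionless) within a subject.  Differentiating a recovered field
  whose error is ~1 mm with a correlation length of one smoothing scale
  produces J fluctuations of sd ≈ 0.2 — nearly an order of magnitude above
  the signal — so the voxel-wise rank correlation of registration-derived
  VI_JAC with truth is ≈ 0.1 even though the field itself is accurate to
  half a voxel, and neither stronger regularization, high-pass or
  mass-compensated forces, post-hoc field smoothing at 6–24 mm, nor a
  B-spline-subspace-constrained variant raises it above ≈ 0.16.  The same
  code with the analytic true field scores rs ≥ 0.999, isolating the effect
  to registration error.  This reproduces, on synthetic data, the clinical
  observation that registration-based ventilation can correlate near zero
  with a reference even when the registration looks good.
* **Six training subjects cap the learned regressor.**  The held-out mean
  Spearman vs truth reaches ≈ 0.56 at desk scale, about 70% of the
  label-vs-truth ceiling (the degraded reference itself correlates 0.69–0.94
  with truth per subject).  Per-subject 90th-percentile label normalization
  also makes the target scale subject-relative, which a per-slice model
  cannot fully resolve.
* The demons implementation is not diffeomorphic and makes no guarantee of
  positive Jacobians for large motions.
* Airway removal is a deterministic midline-corridor heuristic adequate for
  phantoms, not a clinical airway segmenter.
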