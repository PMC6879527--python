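# Methods

## Problem and model

The package detects periodontal bone loss (PBL) per tooth in panoramic
dental radiographs and reports the affected teeth in FDI (ISO-3950)
notation. Because per-tooth positive examples are scarce and imbalanced,
the method is multi-phase rather than a single classifier:

1. **Annotator aggregation.** L annotators (default 5) supply per-tooth
   binary labels and pixel lesion masks. Tooth labels are combined by vote
   thresholding, `y_j = 1` iff at least `C_R` annotators marked tooth j
   (`C_R = 3` of 5, majority voting). Lesion masks are combined per pixel
   at threshold `C_S`; `C_S = 1` (the union) is used for segmentation
   supervision to favour recall.
2. **ROI segmentation.** A U-shaped encoder-decoder is trained to segment
   the arch-shaped teeth band, with per-pixel binary cross-entropy plus an
   L2 weight penalty `(λ/2n) Σ w²` (λ = 1e-4). Predicted masks are
   post-processed by hole filling then convex hull, and the bounding box of
   the result is cropped, resized, background-zeroed and z-scored over
   in-mask pixels.
3. **Lesion-segmentation pre-training.** A second U-net of the same shape
   is trained on the union masks with a per-pixel focal loss
   `-(1/n) Σ [(1-p)^γ y log p + p^γ (1-y) log(1-p)]`, γ = 2, so the rare
   lesion pixels dominate the gradient. Its encoder initializes the
   classifiers (all layers remain trainable).
4. **Tooth-level classification.** A generalist `f_A` maps the full ROI
   crop to 32 sigmoid scores; a specialist `f_B` sees a vertical half of
   the crop (doubling the effective sample count) with incisor/canine
   labels zeroed and is responsible for premolars/molars. Training
   minimizes the per-tooth focal loss (γ = 2, plus the L2 penalty) plus
   `β = 0.01` times an auxiliary co-occurrence loss per jaw:
   the 16 scores of a jaw are pulled toward the target
   `c = C y / max_j (C y)_j`, where `C` is that jaw's co-occurrence
   matrix built from training labels (`C_jj'` = joint positive frequency).
   An all-negative mouth maps to the all-zero target.
5. **Ensembling.** Incisor/canine scores come from `f_A`; premolar/molar
   scores are `α f_A + (1-α) f_B`, α = 0.1, with `f_B` evaluated on the
   half containing the tooth (FDI quadrants 1/4 on the image's left half,
   the standard panoramic orientation).
6. **Evaluation.** All metrics are micro-averaged over (image, tooth)
   decisions. Operating points are chosen on validation scores only:
   `balanced` maximizes F1 over the grid of observed scores plus {0, 1};
   `high_sensitivity` / `high_specificity` match the worst simulated
   clinician's specificity / sensitivity by nearest absolute difference,
   ties toward the higher threshold.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `C_R` | 3 of 5 | tooth-label vote threshold (majority) |
| `C_S` | 1 of 5 | lesion-mask vote threshold (union) |
| γ | 2 | focal-loss exponent, both pixel and tooth losses |
| λ | 1e-4 | L2 weight penalty scale |
| β | 0.01 | weight of the auxiliary co-occurrence loss |
| α | 0.1 | generalist share for premolar/molar ensembling |
| clamp ε | 1e-7 | probability clamp before any logarithm |

Full-scale settings (512x1024 inputs, 50/100 epochs, learning rates
1e-4/1e-5) remain expressible through `SegmenterConfig` and
`ClassifierConfig`. The desk-scale experiments in `pblnet.pipeline` use
64x128 inputs, U-nets with 8 base channels (depth 2 for the ROI net,
depth 3 for the lesion net and classifier encoders), Adam at 1e-3, and
small epoch counts (10/15/30); these are the package's chosen problem
sizes for CPU-scale runs and are also what the test suite and
`scripts/acceptance.py` exercise.

## Architecture choices

The segmenters are standard U-nets (two 3x3 conv + ReLU per level, 2x2
max pooling, nearest-neighbour upsampling, skip connections by channel
concatenation, 1x1 sigmoid head). The classifier reuses the encoder
(downsampling path plus bottleneck) and attaches two conv blocks, global
average pooling, and two fully connected layers ending in 32 sigmoid
outputs.

Global average pooling is translation invariant, but assigning a lesion
to a tooth *index* requires absolute position. The head therefore
receives the encoder features concatenated with two fixed normalized
coordinate channels (row and column in [-1, 1]) before its conv blocks.
This keeps the transferred encoder unchanged (its input stays the
1-channel crop) while letting pooled features carry position.

Joint training of `f_A` and `f_B` alternates per batch over a shared
loader: `f_A` updates on the full crops, then `f_B` updates on both
vertical halves of the same batch. `f_B` keeps the full 32-way output;
its targets zero the incisor/canine entries and additionally the teeth of
the absent half. Halves are disjoint, so midline teeth may be truncated
at the split; this is accepted and noted.

Grad-CAM uses the last head convolution before global average pooling as
the target layer and backpropagates from the pre-sigmoid logit (the
sigmoid saturates for confident scores and would shrink gradients to
numerical noise); channel weights are spatially averaged gradients, and
the ReLU-rectified weighted sum is max-normalized and bilinearly
upsampled to the crop. Because the map lives on a 2^depth-downsampled
grid (8 px cells at desk scale), localization checks allow a margin of
two feature-map strides around the lesion bounding box. Whether a trained
model's maps localize well is itself stochastic across training runs -
models with indistinguishable AUROC can attend to different cues - so the
localization property is assessed over several independent training runs
and required to hold for the majority.

The training engine is a small NumPy reverse-mode autodiff (float32,
stride-1 convolutions as offset matmuls, Adam). All randomness flows
through explicit seeded generators, so every training entry point is
bit-reproducible per seed on a given platform.

## Numerical conventions

- Probabilities are clamped to [1e-7, 1 - 1e-7] before logarithms; the
  clamp passes gradients only where not active.
- `dice(∅, ∅) = 1`; a zero-variance crop z-scores to zeros instead of
  dividing by a vanishing standard deviation (floor 1e-8).
- The per-tooth focal loss averages over all (sample, tooth) entries (not
  summed over teeth) so its scale is independent of batch and output
  sizes; the auxiliary loss sums over the 16 teeth of a jaw and averages
  over the batch.
- The convex hull is rasterized explicitly: a pixel belongs to the hull
  when its center satisfies all half-space inequalities of the hull of
  foreground pixel centers up to 1e-9. Degenerate foregrounds (fewer than
  3 points, collinear) are returned unchanged after hole filling. This
  pins boundary semantics exactly, which the tests verify against an
  independent flood-fill + polygon oracle.
- Image resizing is bilinear; masks use nearest-neighbour so they stay
  binary. Undefined metric ratios (zero denominators) are reported as
  absent, never as 0.

## Synthetic data: what it does and does not emulate

The generator renders an arch-shaped band containing 32 bright
tooth-like ellipses in the FDI layout inside a noisy background with
random collimation margins and intensity jitter (the field-of-view
variability of real panoramic devices). Positive teeth receive a dark
wedge at the tooth neck whose size scales with a severity draw,
mimicking the focal radiolucency of bone loss.

Tooth labels come from an autologistic chain along each jaw, visited
left to right: the conditional log-odds of a lesion shift by
±`adjacency_coupling` (default 1.0) with the previous tooth's state,
damped by `end_damping` (0.3) at steps touching a third molar. This
yields the banded co-occurrence structure of adjacent teeth with weakly
coupled third molars, and exact independence at zero coupling. Base
prevalence is 0.25 per tooth; five simulated annotators flip each tooth
label independently at rate 0.1 and perturb each lesion component by
omission (rate 0.1), ±1 px shifts, dilation/erosion, and occasional
spurious blobs (rate 0.05).

Passing tests on this generator demonstrate that the pipeline's
machinery works end to end - aggregation recovers the truth, the
segmenters learn separable structure, transfer helps, the ensemble and
metrics behave as specified. It does not demonstrate clinical
performance: real radiographs have anatomy, superimpositions, device
artifacts and lesion morphology the generator does not model, and the
published clinical figures require the original hospital dataset.

## Design decisions that were genuinely open

- The co-occurrence matrix is a joint-occurrence frequency (count / N).
  The auxiliary target is invariant to positive rescaling of the matrix,
  so counts, frequencies or correlations yield the same loss; frequency
  is the simplest symmetric choice.
- Classifier training at desk scale uses no geometric augmentation: a
  10% shift at 64x128 moves a tooth by roughly two tooth pitches while
  its label index stays fixed, which destroys the position-label
  correspondence the head must learn. The segmentation stages keep the
  full augmentation (rotation <= 10 deg, shifts <= 10%, photometric
  jitter <= 15%) since their masks transform jointly with the image.
- "Sharpness" jitter is implemented as unsharp-mask blending with
  strength within +/-15%.
- The transfer ablation uses a fixed budget of 40 minibatch updates with
  identical batch order for both initializations; the budget is small
  enough that initialization quality still shows in the training loss.

## Known limitations

- The co-occurrence matrices use raw joint frequencies, so rare teeth
  (third molars) contribute weak auxiliary targets; a dedicated
  third-molar model is out of scope.
- The desk-scale networks are far smaller than clinical-scale models;
  absolute dice/AUROC values on synthetic data do not transfer to real
  radiographs.
- `f_B`'s disjoint half inputs may truncate midline teeth.
- Bit-reproducibility holds per platform/BLAS build; cross-platform runs
  may differ in the last float32 ulp.
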