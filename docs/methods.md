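# Methods

## Problem setting

A bone marrow smear slide carries a single diagnostic label — one of the
five common hematological malignancies AML, ALL, CML, CLL, MM — but the
evidence for that label lives in a small fraction of the slide's area.
Pixel- or cell-level annotation at scale is impractical, so the package
treats the task as multiple-instance learning (MIL): a slide is a *bag*
of 256×256 patches, only the bag is labeled, and the model must both
classify the bag and discover which patches carry the evidence.

## Preprocessing

Slides are segmented at a 16× downsampled resolution: the image is
block-mean downsampled, converted to grayscale luminance, and
Otsu-thresholded; the *dark* class is the foreground, because smear
material is darker than the bright-field background. Otsu is implemented
on a 256-bin histogram as the exact argmax of between-class variance over
all split levels, ties resolved to the smallest level, and is verified in
the tests against an exhaustive search (and against scikit-image within
one bin). An optional saturation-channel mode is not provided; grayscale
was sufficient for bright-field smears, which is the only imaging mode in
scope.

Tiling enumerates 256×256 windows on a stride grid — stride
`round(256·(1−overlap))`, overlap 0 for classification and 0.5 for
heatmaps — and keeps a window when its foreground fraction on the mask
grid reaches `min_foreground_fraction` (default 0.5; there is no
field-standard per-patch retention rule, so the value is exposed in the
API and CLI). Window coordinates are 0-based, half-open, in level-0
pixels. Partial edge windows are dropped for slides (interior tissue is
abundant) but padded with the background color for micrographs, whose
complete 30–70-patch grids form one bag per image; micrographs are first
rescaled by `target_magnification / source_magnification` (target 10×).

Only flat images (PNG/JPEG/TIFF) are read. Pyramidal scanner formats
would need a dedicated multi-resolution reader; the preprocessing
operates on whichever single level is handed to it, which is also what
the synthetic fixtures produce.

## Feature encoding

Each patch is encoded frozen (no gradients ever reach the encoder) into
a fixed-length vector, 1024-d by default, through a pluggable `Encoder`
contract. The shipped encoder mean-pools the patch on an 8×8 grid and
applies a fixed seeded Gaussian linear map (float64 internally, float32
out), so it is bit-deterministic, needs no downloaded weights, and
preserves the coarse color-layout statistics that distinguish the
synthetic fixtures. A learned CNN encoder drops into the same contract;
nothing downstream depends on how the vector was produced, only on its
dimension. Bags are stored one HDF5 file per slide (`features` K×D
float32, `coords` K×2 int64, attributes slide_id/label/magnification/
encoder_name).

## The classifier

For a bag of K features h_k ∈ R^D:

1. **Fc stack** — two affine+ReLU layers, D→512→512, give embeddings
   h_k ∈ R^512.
2. **Gated attention** — a shared trunk computes
   tanh(W₁h_k) ⊙ σ(W₂h_k) with W₁, W₂ ∈ R^384×512; N per-class heads
   P_i ∈ R^1×384 give raw scores e_{i,k}, and each branch's attention
   a_i = softmax_k(e_{i,·}) is a distribution *over the patches of the
   bag*. (Normalizing over classes instead would not yield per-branch
   distributions over patches and makes the pooling step meaningless;
   the per-patch softmax is the only consistent reading.)
3. **Pooling and scoring** — h_slide,i = Σ_k a_{i,k} h_k; logits
   s_i = W_c,i h_slide,i + b_i, probabilities softmax over the N logits.
4. **Instance clustering** — in the true class's branch, the B
   most-attended patches are pseudo-labeled positive and the B least
   negative (B clamped to ⌊K/2⌋; ranking by a stable ascending sort on
   (score, index), so ties resolve deterministically and the sets are
   always disjoint). A per-branch linear 2-way instance classifier is
   trained on the 2B embeddings with the smooth top-1 SVM loss
   L(s, y) = τ·log Σ_j exp((s_j + 1[j≠y] − s_y)/τ), which approaches the
   multiclass hinge as τ→0. Only the in-class branch is supervised; for
   mutually exclusive subtypes out-of-class negatives are a defensible
   extension but are not enabled because the bag loss already pushes
   out-of-class attention down.

Total loss = c1·CE(bag) + c2·L(instances) with defaults c1 = 0.7,
c2 = 0.3 and τ = 1 (the conventional values in clustering-constrained
attention MIL; no principled alternative exists without a validation
study, and all three are exposed parameters). Dropout p = 0.3 follows
each Fc ReLU and the gated trunk — never the attention distribution
itself, which must stay on the simplex.

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `input_dim` | 1024 | encoder output dimension |
| `embed_dim` | 512 | Fc embedding width |
| `attn_dim` | 384 | attention trunk width |
| `dropout` | 0.3 | dropout probability, training only |
| `B` | 8 / 32 / 128 | instance-cluster sample per bag, preset by objective (10×/40×/100×) |
| `bag_loss_weight` / `instance_loss_weight` | 0.7 / 0.3 | loss mix |
| `svm_tau` | 1.0 | hinge smoothing temperature |
| `learning_rate` | 2·10⁻⁴ | Adam, batch size one bag |
| `max_epochs` / `patience` | 200 / 20 | early stopping on validation loss |

## Implementation of training

The model is plain NumPy with hand-derived analytic gradients and a
hand-rolled Adam (β = 0.9/0.999, ε = 10⁻⁸): at bag-at-a-time batch sizes
the tensors are small enough that a deep-learning framework buys nothing,
and an explicit backward pass makes the gradient checkable — the test
suite verifies analytic against central-difference gradients on a random
sample of every parameter tensor (relative error ≤ 10⁻³; the check runs
with dropout off, since finite differences are meaningless through a
resampled mask). The top/bottom-B selection is treated as a constant of
the backward pass, the standard convention for hard top-k.

Early stopping: "no improvement" means no decrease of at least 10⁻⁶
below the running best validation loss; after `patience` consecutive
non-improving epochs training stops and the parameters of the *best*
epoch (not the last) are returned. A forced never-improving validation
sequence therefore runs exactly 1 + patience epochs. Per-epoch bag order
is reshuffled from a seed derived from `random_state` and the epoch
index, so runs are bit-reproducible. Non-finite training loss aborts
with a diagnostic rather than continuing.

Numerical conventions: softmaxes subtract the row max; the smooth SVM
uses a log-sum-exp with the same shift; bag cross-entropy clamps the
probability at 10⁻³⁰⁰ before the log.

## Evaluation protocol

Monte Carlo cross-validation: each fold is an *independent* stratified
resample — per class of size n_c, `round(0.6·n_c)` train,
`round(0.2·n_c)` validation, remainder test, each split guaranteed
nonempty (so classes need ≥ 3 members) — rather than a disjoint k-fold
partition; folds share slides at random. Metrics: macro-averaged
one-vs-rest AUC (per-class AUC of that class's probability column
against the rest; classes missing a positive or negative are skipped
with a warning), balanced error (mean over classes of 1 − recall),
accuracy, and the mean ± sd of the winning probability split by
correctness (an empty group is reported absent, not zero). Slide-level
feature maps use the predicted class's pooled representation h_slide,ŷ
projected onto the top-2 principal components; a flag to concatenate all
branches was considered and rejected as it mostly visualizes branch
identity rather than disease structure.

## Heatmaps

For interpretation the slide is re-tiled at 50% overlap, patches are
encoded and scored with one branch's attention (default: the predicted
class), raw scores are min–max normalized to [0,1] across the slide
(a slide with a single distinct score maps to 0.5 by convention), and
every map pixel takes the mean normalized score of the patches covering
it. Maps live at the segmentation downsample (16×), which matches the
resolution such overlays are displayed at; uncovered pixels carry an
explicit coverage flag rather than a fake zero. Percentile-rank
normalization is a reasonable alternative when a few patches dominate
the score range; min–max is the default because it preserves relative
score gaps.

## Synthetic data: what it emulates and what it does not

Feature bags: instances are isotropic Gaussians in feature space; each
bag of class c holds ⌈evidence_fraction·K⌉ instances displaced by δ
along a class direction u_c (rows of a seeded orthonormal basis, so all
class pairs are equidistant at δ√2), the rest shared background, with
K uniform on [30, 70] — the bag-size range of real micrograph bags.
Defaults: 5 classes, evidence fraction 0.10 (diagnostic area is a small
minority of a smear), noise sd 1, δ = 6 for the separable condition
(instance-level Bayes error ≈ 1.3·10⁻³, so failures are attributable to
the MIL machinery, not to irreducible noise) and δ = 0 for the null.
All splits of one spec share u_c — the train/test link that makes
generalization measurable.

Pseudo-slides: dark elliptical blobs on a bright near-white canvas;
evidence blobs take a class color inside a random region and are also
emitted as a pixel mask; distractors are neutral gray at a Poisson
density per 10⁴ px². This exercises segmentation, tiling, encoding and
heatmaps end to end with known ground truth.

Neither generator models cell morphology, staining variation, scanner
artifacts, or the spatial correlation of real tissue. Passing the
synthetic benchmarks therefore demonstrates that the machinery —
attention pooling, instance clustering, training protocol, localization
— is correct and recoverable under the stated statistical structure; it
does not certify clinical performance, which depends on a real cohort
and a learned encoder.

## Benchmark problem sizes

The packaged benchmark (`hemamil.experiments.run_synthetic_benchmark`)
trains on 25 bags per class with 8 validation and 8 test bags per class,
256-d features, the 10× preset (B = 8), lr 2·10⁻⁴, patience 20. These
sizes keep a full run in the minutes range on a single CPU while leaving
40 test bags to score; they are the package's desk-scale stand-in for a
cohort-scale study.

## Known limitations

- No pyramidal (multi-resolution) slide reader; callers supply a single
  resolution level.
- The shipped encoder is a fixed linear map over pooled color statistics;
  real-morphology discrimination requires plugging in a learned CNN
  encoder.
- Instance clustering supervises only the in-class branch.
- Monte Carlo folds share slides across folds by construction; fold
  metrics are correlated, and the reported sd understates variance
  accordingly (a property of the protocol, not of this implementation).
- Training is single-threaded bag-at-a-time; cohort-scale training with
  a deep encoder would need a GPU framework, for which the model here
  serves as the reference semantics.
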