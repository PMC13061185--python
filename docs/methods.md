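# Methods

This note documents the model, the evaluation protocol, the synthetic data
that stands in for clinical images at desk scale, and the numerical and
design choices behind both. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Network

MaxGRNet is a hierarchical multi-axis vision transformer. The stem applies
two 3×3 convolutions (the first with stride 2); each of the four stages
S1–S4 then repeats a block of

1. **MBConv** — channel-wise pre-norm, 1×1 expansion (ratio
   `mlp_expansion`), 3×3 depthwise convolution (stride 2 in a stage's first
   block, which also switches the channel width), squeeze–excitation gating
   (reduction `se_ratio`, sigmoid gate), 1×1 projection, and a residual whose
   shortcut is 2×2 average-pooled and 1×1-projected when downsampling;
2. **block attention** — pre-LayerNorm multi-head self-attention with a
   learnable relative-position bias inside non-overlapping `P×P` windows,
   plus residual;
3. **grid attention** — the same operator over `P×P` groups sampled every
   `H/P` pixels, so each group spans the whole image (global mixing at
   linear cost), plus residual;

with a residual **GRN-MLP** after each attention operator: LayerNorm →
expand (`mlp_expansion`) → GELU → Global Response Normalization → project.
GRN computes, per sample, the spatial L2 norm `g_c` of every channel,
divides by the cross-channel mean (`n_c = g_c / (mean_c g + ε)`,
`ε = 1e-6`), and returns `γ_c·x·n_c + β_c + x`. The head is global average
pooling → LayerNorm → linear.

Choices a reader may want to know:

* **GRN parameters.** The recalibration is often described as
  parameter-free; the formulation adopted here carries learnable per-channel
  γ, β initialized to zero, so the operator is the identity at
  initialization, and `grn_frozen=True` pins them at zero for the
  strictly parameter-free reading. `grn_enabled=False` removes the step
  entirely (plain MaxViT-style block); at γ = β = 0 both paths agree
  exactly, which the tests verify.
* **GRN scope.** The spatial L2 aggregation runs over the full feature map
  by default (`grn_scope="full"`); a per-window variant is available
  (`"window"`). Full-map aggregation is the natural reading of a *global*
  response normalization and makes the MLP identical for the block- and
  grid-attention positions.
* **GRN placement.** After the nonlinearity, before the projection — the
  placement of the formulation GRN originates from.
* **Normalization.** LayerNorm over the channel axis everywhere (token
  LayerNorm in attention/MLP, per-position channel LayerNorm in MBConv), so
  inference is batch-independent.
* **Partitioning is strict.** Spatial sizes must be divisible by `P` at
  every stage; there is no implicit padding, because silent padding changes
  the attention semantics. `ModelConfig.validate()` enforces this at
  construction.
* **Initialization.** Truncated normal (σ = 0.02, clipped at 2σ) for
  attention/MLP projections — these sit on residual branches and should
  start near-silent — but fan-in–scaled truncated normal for convolutions,
  which carry the main signal path; zeros for biases, γ, β. A model is a
  pure function of `(ModelConfig, seed)`.
* **Default configuration** mirrors the tiny tier of the architecture
  family: depths (2, 2, 5, 2), widths (64, 128, 256, 512), stem 64, `P=7`,
  expansion 4, SE ratio 0.25, head width 32, input 224².
  `ModelConfig.tiny()` (input 64², widths 8–64, `P=2`, ~125k parameters) is
  the CPU-scale configuration used throughout the tests.

The whole network runs on an in-package reverse-mode autodiff core over
numpy (`autodiff.py`): broadcast arithmetic, matmul, reductions, shape ops,
fused GELU, dense/depthwise conv2d via im2col with scatter-add backward, and
integer gather for the relative-position tables. Gradients are retained on
interior nodes, which is what lets Grad-CAM read `∂logit/∂feature` at any
layer after one backward pass. Correctness is pinned by central-difference
tests on every primitive.

## Training and evaluation

Training is plain cross-entropy with Adam (L2 weight decay folded into the
gradient), seeded shuffling, and per-epoch train/validation accuracy
history. The default `TrainConfig` carries the full-scale study settings
(50 epochs, batch 64, learning rate 1e-5, weight decay 3e-5); the desk-scale
runs in the tests use 4–10 epochs, batch 16 and learning rate 1e-3–2e-3,
which a 125k-parameter model needs to converge from scratch in seconds.
Supplying sample ids makes any train/eval overlap a hard `LeakageError`.

Metrics are per-class one-vs-rest TP/FP/TN/FN with accuracy
(TP+TN)/N, precision, recall, F1; macro values are unweighted class means,
overall accuracy is trace/total, and zero denominators report 0 with a
logged warning (the convention only matters for degenerate inputs).
One-vs-rest ROC AUCs come from scikit-learn's trapezoid ROC; classes absent
from the truth are excluded from the macro with a warning. Cross-validation
uses stratified folds (shuffled, seeded; `stratify=False` available),
a fresh model per fold, augmentation only inside a fold's training split,
and ddof=1 across folds.

Statistics: percentile bootstrap (default 10⁴ replicates) for mean CIs;
paired *t* with the t-distribution CI on the mean difference (df = n−1);
Wilcoxon signed-rank with zeros dropped and mid-ranks for ties, exact by
dynamic-programming enumeration of the signed-rank distribution for n ≤ 25
and the normal approximation beyond; Holm–Bonferroni step-down (via
statsmodels) applied across one family of contrasts at a time. Per-image
faithfulness comparisons pair results by image id on the common subset.

## Saliency and faithfulness

Grad-CAM uses the pre-softmax logit as the class score (hence invariance to
constant logit shifts), channel weights equal to the spatial mean of the
gradient at a chosen feature layer, rectification after the weighted sum,
and bilinear upsampling to input resolution. The default layer is the
depthwise convolution of the final stage's last MBConv ("last convolutional
layer"); every tap is addressable by name and the error message lists them.
No normalization is applied before faithfulness ranking — only the order
matters; `SaliencyMap.normalized()` exists for visualization.

Deletion replaces the top-ranked pixels (all three channels) with a
Gaussian-blurred copy of the same image; insertion restores them into that
blurred copy. Defaults follow the reference protocol: kernel 51, σ = 8.0,
50 steps; step sizes partition the pixel count as evenly as possible with
the remainder spread over early steps; saliency ties break by row-major
pixel index. The blur is separable Gaussian filtering with an explicit
radius of (kernel−1)/2, so `kernel=1` is the identity. A `baseline=`
argument admits a zero baseline for closed-form toys. Curves are softmax
confidences, so they live in [0, 1]; AUC is the trapezoid rule over the
stored fractions. `evaluate_faithfulness` applies the correct-only protocol
(misclassified images excluded, target class = predicted class), evaluates
all steps of one curve in a single batched forward pass, and summarizes with
percentile-bootstrap CIs.

## The phantom generator

`synthetic_fundus` draws a warm, radially shaded disc on black and adds one
class-specific lesion per image, with a binary ground-truth mask:

* *normal* — plain disc, empty mask;
* *cataract* — a broad central veil of bright/dark flecks;
* *retinopathy* — a compact cluster of bright exudate-like and dark
  haemorrhage-like dots in the upper temporal quadrant;
* *glaucoma* — an enlarged cup drawn as a bright rim with a dark inner ring.

Three generator properties are deliberate, because the downstream tests
need them simultaneously:

1. **Lesions are high-frequency and near zero-mean at the blur scale.**
   Bright and dark elements are colour-balanced against the local disc
   colour, so the σ = 8 blur genuinely erases the class evidence — otherwise
   deletion curves stay flat and faithfulness is unmeasurable. (The paired
   bright/dark colours were chosen so their average approximates the local
   disc colour per channel; a residue survives for the veil class, whose
   blurred confidence stays midscale.)
2. **Each class's lesion layout is a fixed, class-keyed pattern** (same
   fleck/dot lattice across images, with small per-image jitter). Images of
   one class therefore resemble each other in raw pixel space, which is what
   makes a 3-nearest-neighbour classifier on 16×16 block-averaged pixels
   separate the classes (≥90 % held-out accuracy, verified across seeds) —
   position-randomized zero-mean textures provably defeat raw-pixel kNN,
   because within-class distances exceed cross-class distances by √2.
3. **Per-image child seeds** (`default_rng([seed, label, index])`) make every
   image independent of the rest of the dataset's composition.

A nuisance brightness factor (0.85–1.05) discourages global-intensity
shortcuts. The generator's purpose is exercising the classification,
saliency and faithfulness pipeline end to end; it does not emulate vessel
trees, acquisition artefacts, inter-clinic variation, or the visual
difficulty of real fundus photographs. Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline at desk scale, not
clinical performance.

## Desk-scale study conditions

The session-scoped fixtures pin one configuration, chosen once as the
package's study conditions:

* cohort: 4 × 50 phantom images, seed 1; split 150 train / 50 validation;
* fixture model for saliency/faithfulness: `ModelConfig.tiny()`, weight
  decay 2e-3, 10 epochs, learning rate 1e-3, batch 16 — the stronger weight
  decay regularizes the network toward cleaner gradient attribution, which
  Grad-CAM needs; the separate trainability check uses weight decay 3e-5
  and reaches ≥95 % validation accuracy in the same 10 epochs;
* Grad-CAM layer for the faithfulness suite: `stage2.block0.out`
  (16×16 resolution — fine enough to resolve lesions, deep enough to be
  class-discriminative);
* faithfulness sweep: 100 correctly classified lesion-class images,
  blur (51, 8.0) with 8 curve steps — the coarser step count samples the
  same curve shape at 64² resolution and keeps the sweep tractable; the
  protocol default remains 50;
* scaled-down cross-validation: 4 × 30 images, 5 folds, 6 epochs.

Known limitation, stated plainly: at this scale, Grad-CAM's localization
quality varies with the training trajectory. Global grid attention and the
GRN/SE global pooling delocalize gradients, and heavily converged models
drift toward blur-robust, spatially distributed features; the pinned
fixture (moderate training plus stronger weight decay) sits in the regime
where the map is meaningfully localized — the mass-concentration test
verifies this rather than assuming it. The faithfulness ordering
(Grad-CAM above random on insertion, below on deletion) and the
lesion-mask oracle's dominance over random ranking are then reproduced
deterministically by the seeded suite.

## Data pipeline

Real-image ingestion indexes class-per-subdirectory trees into a DataFrame
(`image_id` = path hash; augmented ids = parent id + copy ordinal).
Preprocessing resizes bilinearly to 224² (aspect ratio not preserved),
scales to [0, 1] and normalizes with the ImageNet channel statistics;
grayscale inputs replicate to three channels with a warning. Augmentation
composes horizontal/vertical flips (p = 0.5 each), brightness/contrast/
saturation jitter (factor 0.2) and Gaussian blur (kernel 3, σ ∈ [0.1, 2]),
all from one per-call seed. Holdout splits are stratified with
largest-remainder rounding. Class balancing is strictly split-then-augment:
the per-class target divides over subsets proportionally (default 70/20/10 →
1400/400/200 for a 2000 target), each cell's deficit is assigned round-robin
over a seeded shuffle of that cell's real parents, and
`verify_no_leakage` returns (rather than raises) the list of violations —
an augmented record whose subset differs from its parent's, or duplicate
ids. Balancing evaluation subsets inflates them with synthetic variants;
`--no-eval-augment` restricts balancing to the training subset.

## Orchestration

The CLI (`maxgrnet …`) wraps the library one command per stage and writes a
manifest (command, config, seeds, input fingerprints, outputs, timestamp)
beside every artifact. Checkpoints are numpy `.npz` weight archives with a
YAML `ModelConfig` sidecar. All stochastic behaviour flows from explicit
seeds; there is no unseeded randomness anywhere in the package.
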