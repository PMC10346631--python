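# Methods

## Model

The network is a one-stage instance segmenter specialised for dense fields
of small, similar objects. Four parts:

1. **Windowed-attention backbone.** Stride-4 patch embedding (4×4 conv +
   layer norm over channels), then four stages of transformer blocks with
   patch merging (stride-2 sub-grid concatenation → LN → linear 4C→2C)
   between stages. Each block is LN → windowed attention → drop-path →
   residual, LN → MLP (hidden = 4×dim, GELU) → drop-path → residual. Blocks
   alternate in pairs: plain windows, then windows shifted by half a window
   with an additive −10⁹ logit mask between tokens from different pre-shift
   regions. Attention is softmax(QKᵀ/√d + B)V per head, with a learnable
   relative-position bias table B indexed by token offset (zero-initialised;
   a fixed-zero option exists for oracle tests).

2. **Six-level pyramid.** 1×1 laterals + nearest-neighbour top-down fusion
   (3×3 smoothing on fused maps), stride-2 3×3 convs for the two coarsest
   levels. One detection scale per level ([12, 24, 48, 96, 192, 384] px =
   3× each level's stride), three area-preserving aspect ratios
   (w = s√r, h = s/√r, r ∈ {1, ½, 2}), anchor centres at pixel centres.

3. **Heads.** Shared two-conv trunk, three sibling 3×3 branches (class, box,
   coefficients), each a 256-channel feature conv plus an output conv. The
   class branch's feature map is added into the box branch's input and the
   box branch's into the coefficient branch's (element-wise; a config switch
   disables fusion for ablations). Coefficients pass tanh so masks can
   subtract prototypes. The prototype net is conv3×3 ×2 → bilinear 2× →
   conv3×3 ×2 → conv1×1 → ReLU: five convolutions, output side twice P1's.

4. **Assembly.** Box deltas decode against anchors in centre-size form with
   variances (0.1, 0.2), clipped to the canvas. Per-class Fast NMS on the
   score-sorted IoU matrix (upper-triangularise, column max, keep ≤ 0.5);
   ties in score break by lower candidate index for determinism. Masks are
   σ(PCᵀ), bilinearly upsampled, cropped to the predicted box expanded by
   5% per side, then thresholded at 0.5. Cropping precedes thresholding so
   prototype activity cannot leak between adjacent grains.

## Training objective

- **Matching:** positive at IoU ≥ 0.5 with the anchor's best truth, negative
  below 0.4, ignored between; every truth force-matched to its best anchor.
- **Classification:** softmax cross-entropy over c+1 classes; hard-negative
  mining caps participating negatives at 3 per positive (ranked by detached
  background loss), averaged over participants. The 3:1 ratio is read as
  negatives:positives, the convention of the one-stage family this design
  extends.
- **Box:** smooth-L1 (quadratic inside |x| < 1, linear outside; gradient
  magnitude ≤ 1 per coordinate) on encoded deltas, summed over the four
  coordinates and averaged over positives.
- **Mask:** per positive anchor, BCE between σ(P·c) and the matched truth
  mask at prototype resolution (area-average downsampling when the factor
  divides, centre-nearest otherwise), weighted to the truth box and
  normalised by its area; truth-box (not predicted-box) cropping is used
  during training. Zero-area truths are skipped with a warning.
- **Total:** 1.0·cls + 1.5·box + 6.125·mask. The component weights are
  unpublished for this architecture; these are the weights of the prototype
  -mask family it derives from, exposed in the `loss:` config section.
- **Optimiser:** AdamW, weight decay 5e-4; linear warm-up 1e-5 → 1e-4 over
  500 iterations, constant afterwards (step decay optional). Batch 8,
  640-px input at paper scale.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `backbone.embed_channels` | 96 | C1 width; doubles per stage |
| `backbone.depths` / `heads` | (2,2,6,2) / (3,6,12,24) | canonical tiny-transformer layout; unpublished for this network, config-overridable |
| `backbone.window_size` | half the map side | yields exactly 4 plain windows / 9 shifted regions per map; a fixed token window with boundary padding is available |
| `pyramid.channels` | 256 | all six levels |
| `head.prototypes` | 32 | k, the prototype/coefficient count |
| `loss.pos_iou` / `neg_iou` | 0.5 / 0.4 | matching thresholds (unpublished; standard values) |
| `run.nms_iou` | 0.5 | Fast NMS threshold |
| `run.top_n` / `max_dets` | 200 / 100 | per-class NMS pool / overall cap (COCO protocol) |

## Evaluator

COCO-protocol mask AP, implemented in-package: greedy per-image/class/
threshold matching in descending score order (each truth used once),
101-point interpolated precision, AP averaged over classes and the ten IoU
thresholds 0.50:0.05:0.95; AP50/AP75 at fixed thresholds; AP_S/M/L restrict
truths by area band (small < 32², medium < 96², large ≥ 96² px), with the
COCO ignore conventions for out-of-band truths and detections. mAP here
means the IoU-averaged metric, matching how the architecture's headline
numbers are defined. Bands with no truths report NaN and are excluded from
means. The evaluator is verified against brute-force precision–recall
integration on hand-built cases, not against an external library.

## Synthetic data

The generator emulates the statistical structure of seed-lot photographs:
many small particles, dense layout, similar appearance. Grains are rotated
ellipses (analytic masks and areas) rejection-sampled under a pairwise mask
IoU bound (default 0.05); each of up to eight classes has a distinct base
colour with within-class jitter (σ = 8 grey levels) small relative to
between-class separation; additive Gaussian texture noise (σ = 5) over a
dark background. Defaults: 640×640 canvas, 40 grains, semi-axes 10–16 × 5–8
px, putting every instance below the 32² px small-object boundary.

What it does **not** model: real grain outlines (superellipse tips, husk
texture), specular highlights, shadows, touching-grain occlusion chains,
illumination gradients, or camera noise statistics. Tests passing on this
data therefore demonstrate that the architecture, losses and evaluator are
wired correctly and can fit dense small-object scenes — not that the model
reaches any particular accuracy on real seed photographs.

## Desk-scale preset and problem sizes

`Config.tiny()` — 128-px input, embed 16, depths (2,2,2,2), heads (1,2,4,8),
32-channel pyramid/head, 8 prototypes, batch 1, drop-path 0 — exists so the
full train/eval cycle is deterministic and runs in minutes on one CPU. Its
learning rate (2e-3, warm-up 10 iterations from 2e-4) is scaled up from the
paper-scale recipe in proportion to the much smaller model and single-image
batch; 300 iterations overfit one 6-grain scene to AP50 = 100. The full-size
(640-px) configuration is exercised forward-only in the shape-contract test;
training it is possible with this engine but far beyond desk scale.

## Numerical choices

- Float32 throughout; layer-norm ε = 1e-5; softmax row-max subtraction;
  sigmoid/BCE in the log1p-stable form.
- Attention logits are processed in blocks of query rows (≈ 2²⁶ elements per
  block) so no full token×token matrix is materialised at 640-px input,
  where stage-1 windows hold 6400 tokens.
- Non-divisible sizes: right/bottom zero-padding before embed/merge/window,
  cropped after — preserving top-left coordinate alignment.
- Upsampling: nearest in the pyramid (cheap, standard for this family),
  bilinear inside the prototype net (smooth masks) — both config-switchable.
- Drop-path rates rise linearly with depth to 0.2 at full scale, 0 in tiny
  mode (determinism).
- All randomness flows from one seed through explicit `numpy.random
  .Generator` objects; checkpoints are `.npz` files keyed by module path.

## Design choices where the source design was open

- The backbone description fixes "four windows" / "nine regions" rather than
  a token window size; the default therefore ties the window to half the map
  side. The standard fixed-window variant is available via config.
- A printed patch-embedding walkthrough (16×16 → 2×2) contradicts the stated
  stride-4 rule (which gives 4×4); the stride-4 rule wins, as only it
  reproduces the printed 160-px C1 at 640-px input.
- The head's fusion operator is unstated; element-wise addition is used
  (preserves channel count and weight sharing). Fusion is taken to inject
  each branch's pre-output features into the next branch's input.
- Whether each pyramid level uses one or all six detection scales is
  ambiguous; one scale per level is used (six scales, six levels).
- Box-delta encoding, matching thresholds, loss weights, mask cropping and
  the coefficient activation are unpublished plumbing; the choices above are
  the established conventions of the prototype-mask detector family.

## Limitations

- CPU NumPy training: practical at desk scale only; no GPU path, no mixed
  precision, no multi-device support.
- Mask AP tie-breaking between equal scores follows insertion order after a
  stable sort; metrics are insertion-order invariant only when scores are
  distinct (true in practice for continuous scores).
- The synthetic domain gap noted above: no claim is made about accuracy on
  real imagery.
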