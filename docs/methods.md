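# Methods

## The model

DSCANet is a dual-branch encoder–decoder for binary polyp segmentation
in colonoscopy frames. The two branches see the same RGB image and
address complementary failure modes: indistinct polyp boundaries and
large variation in polyp size and appearance.

**Edge branch — pixel-difference convolutions.** A vanilla convolution
accumulates weighted intensities, y = Σᵢ ωᵢ·xᵢ. A pixel-difference
convolution (PDC) instead accumulates weighted *pair differences*,
y = Σ₍ᵢ,ᵢ′₎∈P ωᵢ·(xᵢ − xᵢ′), over a pair set P inside the kernel window,
so any locally constant signal produces exactly zero response and the
filter is gradient-aware by construction. We use the central pair set
(every window pixel paired with the window center) by default; an
angular (ring-neighbor) variant is selectable. Implementation folds the
pair weights into an equivalent vanilla kernel (the fold is linear), so
the cost equals a standard convolution; replicate padding keeps the
zero-on-constant property exact at image borders. The branch has four
stages of four residual PDC blocks, x + pointwise(depthwise_pdc(relu(x))),
at widths C_e·(1,2,4,8) with 2×2 max-pooling and channel-doubling 1×1
convolutions between stages, after a two-stride-2-conv stem giving 4×
downsampling. Each stage carries a deeply supervised edge head (1×1 conv
→ sigmoid → bilinear upsampling to input size).

**Body branch — shifted-window transformer.** Non-overlapping 4×4
patches are linearly embedded to C = 96 channels with a learned absolute
positional term, then processed by four stages of window-attention block
pairs with the pre-norm residual layout (W-MSA, then SW-MSA with a
half-window cyclic shift and region masking so tokens wrapped together
from opposite image sides cannot attend), patch merging between stages.
Depths (2,2,6,2), heads (3,6,12,24), window 7, MLP ratio 4, relative
position bias on — the smallest standard configuration of this
window-transformer family. The pyramid is H/4×W/4×C … H/32×W/32×8C.
Windows that do not tile the token grid are zero-padded and the padding
masked out of the attention. Training is from scratch; no pretrained
weights are used anywhere.

**Per-stage fusion.** Stage-wise, edge and body maps are concatenated
and reduced by 1×1 conv + BN + ReLU to the fused widths (96, 192, 320,
384). These fused maps are the decoder's skip connections.

**SCA — spatial cross-attention.** All four *edge* stages are tokenized
to a common count P by average pooling with stage pool sizes PS/2^(i−1)
(PS = 8, so P = 49 at 224² input) followed by a depthwise 1-D
convolution along the token axis. The four token sets are
layer-normalized and concatenated channel-wise; queries and keys are
projected from the concatenation, values from each stage, and a single
attention map Softmax(QKᵀ/√d_k) (d_k = C_c/h_c, h_c = 4 heads) is shared
across all four value streams, so every scale is refined by the same
cross-scale affinity. Refined tokens go through a depthwise projection,
layer norm and GeLU, are reshaped to √P×√P maps, bilinearly upsampled,
and added to the decoder skips after a 1×1 conv + BN + ReLU. A config
switch (`sca_target`) can instead inject them into the body stream
before fusion; the decoder attachment is the default because it is the
operationally specified variant.

**BF — bipolar fusion.** Only the shallowest (1/4) and deepest (1/32)
fused levels are exchanged. Each level is flattened, summarized by a
class token CLS = GAP(Norm(tokens)), given a learnable positional term,
and refined by one standard pre-norm transformer encoder per level
(S = L = 1, MLP ratio 2). The class tokens are then exchanged: the
shallow CLS is projected to the deep width (f_s), used as the *single
query* of a cross-attention over [CLS′_s ∥ deep tokens] — linear cost in
the token count — residually updated, projected back (g_s) and
re-attached to the shallow tokens; mirrored for the deep level. The deep
level operates on a 1×1-reduced 112-wide projection of the 384-wide
fused map (re-expanded afterwards) to keep the module light. The fused
maps replace the decoder's skip connections at stages 1 and 4.

**Decoder with FAA.** A U-shaped decoder (widths 112, 72, 64, 48 from
1/32 to 1/4) upsamples bilinearly, concatenates the (SCA/BF-enriched)
skip, and applies two 3×3 conv-BN-ReLU blocks per stage. The two deepest
stages carry flexible axial-attention (FAA) blocks: height-axis then
width-axis attention, each residual with batch norm, with per-head
relative-position tables r^q, r^k, r^v and four learnable scalar gates

    y_ij = Σ_w softmax_w( q_ijᵀk_iw/√d + G_Q·q_ijᵀr^q_iw + G_K·k_iwᵀr^k_iw )
               · ( G_V1·v_iw + G_V2·r^v_iw ).

Gates start at 1 (plain positional axial attention) and are free to
down-weight positional terms that do not learn well on small medical
datasets. The 1/√d scale on qᵀk is an addition for numerical stability;
the original formulation omits it. After the 1/4-scale stage the decoder
refines progressively through 1/2 (192 channels) and full resolution
(118 channels) with light conv blocks before the single-channel 1×1
logit head, rather than jumping 4× in one step; this avoids blocky
upsampling artifacts and is where most of the model's high-resolution
computation lives.

## Losses

The edge branch uses an annotator-robust, class-balanced log loss per
pixel and stage map: positives (ground-truth confidence ≥ γ) contribute
−β·log p, negatives (confidence 0) contribute −α·log(1−p) with
α = λ·(1−β), and the ambiguous band 0 < confidence < γ is ignored;
γ = 0.6, β = 0.8 (negative-class proportion), λ = 2.0. The per-pixel
losses are summed over pixels and over the four stage maps (a
mean-per-pixel variant is togglable). Predictions are clamped to
[1e−7, 1−1e−7] before logs. The body loss is L_body = λ1·BCE + λ2·Dice
with mean-form BCE, ε-smoothed soft Dice (ε = 1, so matching empty masks
score zero loss), λ1 = 0.6, λ2 = 0.4. The total is
L = L_body + ω·L_edge with ω = 0.3.

## Metrics

All five reported metrics derive from the pixel confusion quadruple:
DSC = 2TP/(2TP+FP+FN), IoU, Precision, Recall, F1 = 2PR/(P+R). DSC and
F1 are the same formula on one quadruple; they differ only across
aggregation modes. The default report averages DSC/IoU/Precision/Recall
per image and computes F1 on globally pooled counts — the only
convention under which the two columns can differ, which is why both
aggregations are exposed. Probability maps are binarized at 0.5.
Zero-denominator convention: 100% when ground truth and prediction are
both empty, else 0%.

## Numerical engine

No GPU framework is used: the package runs on a compact reverse-mode
automatic-differentiation engine over NumPy arrays (`dscanet.autodiff`),
with grouped/depthwise 2-D convolution via im2col + BLAS matmul, pooled
and bilinear resampling expressed as linear operators, and a module
system with Adam, SGD and a reduce-on-plateau schedule
(`dscanet.nn`). Float32 is the working precision; gradient checks in the
test suite validate every primitive against central finite differences.
The same forward pass doubles as the analytic complexity counter: each
matmul and convolution records its multiply-accumulates, and FLOPs are
reported as 2·MACs (one multiply + one add), counting convolutions,
linear layers and attention matmuls; interpolation and weight-folding
are excluded by convention.

## Complexity budget

The architecture targets the method's reference complexity of ~31.25 M
parameters and ~58.63 GFLOPs at 224×224. The original method fixes the body
configuration only loosely ("C-dimensional", a standard window
transformer), so the remaining widths here — edge base width 32, fused
skip widths, BF reduction width, decoder and refinement widths listed
above — were chosen to land on that budget with the Swin-T-scale body
kept intact. The defaults measure 31.28 M and 58.33 G (within 0.6% on
both axes). Parameter count is independent of input size except for the
learned absolute positional terms, which are sized for the configured
input (224 by default); the budget is quoted at 224².

## Synthetic data

The generator emulates the regimes that make clinical polyp segmentation
hard: one or two star-convex blobs (radius r(θ) = R(1 + Σ aₖ sin(kθ+φₖ)),
total perturbation ≤ 0.35 so blob area stays within a factor ~2 of πR²)
on a reddish low-frequency sinusoidal mucosa texture, with contrast
offsets drawn from (0.15, 0.55), boundary softening by a Gaussian of
σ = 1.5 px (blurred boundaries), per-channel color shifts ±0.15,
additive Gaussian noise σ = 0.02, and a radius range (0.06, 0.30) of the
image side spanning tiny to large polyps. Everything is determined by
(seed, index). Edge ground truth is the binarized morphological gradient
(3×3 cross, replicate border) of the mask — the derivation from masks is
not specified by the method and this reconstruction is standard and
parameter-free. What the synthetic data does **not** contain: specular
highlights, vignetting, instruments, motion blur, multiple tissue types,
or realistic polyp texture. Passing tests on it therefore demonstrate
that the architecture, losses, metrics and training loop are implemented
correctly and can fit data of this structure — not clinical-level
accuracy on real colonoscopy.

## Training defaults and the desk-scale harness

The method's reference training conditions are the defaults: Adam, lr 0.01, weight
decay 0.01, ReduceLROnPlateau(patience 5, factor 0.5, min_lr 1e−6),
batch 16, 200 epochs, 224×224 inputs, augmentations of random
horizontal/vertical flips, rotation (±30°) and brightness/contrast/
saturation jitter (±0.2 — ranges the method leaves open, recorded in
config). The best-by-validation-DSC checkpoint is kept; a non-finite
loss aborts with the last finite-loss parameters.

The desk-scale harness used by the tests runs a reduced model — C = 24,
depths (1,1,2,1), window 4 (a 7-window does not tile the 16-token grid
of a 64² input), proportionally narrow decoder — on eight synthetic
64×64 samples for 30 epochs. Its optimizer settings are the harness's
own: Adam lr 2e−3, batch 2, no weight decay, global-norm gradient
clipping at 5; the reference lr 0.01 is tuned to batch-16 training at 224²
and is unstable at this micro-scale. The segmentation and edge heads are
bias-initialized to −2 (foreground is rare; starting from a background
prior removes the early epochs spent deflating the logits). Under these
conditions the full reduced model and the module-free baseline both
overfit to >90% training DSC within 30 epochs in a few minutes of CPU
time. Convergence at this scale is seed-sensitive: on some data seeds
30 epochs reach only the mid-80s; the harness seed is fixed and
reported rather than the band widened.

## Design choices on genuinely open points

- **Edge ground truth from masks**: morphological gradient (above).
- **PDC pair set**: central; the original method names only the PDC family.
- **SCA attachment**: the method description says both "to the body encoder" and
  "to the decoder"; the decoder-skip attachment is implemented as the
  default since that passage specifies the full operator sequence.
  All four levels are refined; the "particularly highest and lowest"
  phrasing is not special-cased.
- **BF input stream**: the post-SCA fused stream (the architecture
  figure places BF after encoder fusion); outputs replace decoder
  skips 1 and 4.
- **FAA placement**: the two deepest decoder stages ("high-level
  features"); gate init 1.0.
- **Validation split**: the experiments mention a validation set without
  defining one; an optional validation fraction (default 0) is exposed,
  with training-set metrics standing in when absent.
- **Eq-form ambiguities**: mean-form BCE, standard ε-smoothed Dice, and
  the reconstructed edge loss are used where the original statements are
  corrupted or ambiguous; sum-forms are behind config flags.

## Known limitations

- CPU-only and NumPy-based: full-scale 224² training at batch 16 for 200
  epochs is supported by the code path but impractically slow compared to
  a GPU framework; the package's verified surface is the desk scale.
- Benchmark-scale results on Kvasir-SEG / CVC-ClinicDB (DSC ≈ 95%)
  require those datasets and long training; they are out of the tested
  scope, and nothing here validates clinical performance.
- BatchNorm statistics lag at very small batch sizes; evaluation uses
  running statistics, which can trail training-mode performance by a few
  DSC points in short runs.
- The positional embeddings tie a built model to its configured input
  size; there is no interpolation of positional tables across sizes.
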