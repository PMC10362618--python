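# Methods

`foveaseg` implements an importance-aware segmentation network for
histopathology lesion tiles.  This note records the model, the choices made
where the design was genuinely open, the numerical conventions, and what the
synthetic experiments do and do not establish.

## The model

**Fovea Pooling (FP).**  Standard encoders blur everything equally when they
pool.  FP instead scores every spatial position of a feature map with an
importance value and pools each position with a radius that *shrinks* as
importance grows, in analogy with the retinal fovea: diagnostically relevant
regions keep full resolution while the rest contributes wide-field context.

The importance module is a pointwise spatial attention block with two
branches.  Each branch maps the (channel-reduced) feature through two 1×1
convolutions to an over-complete embedding with (2H−1)(2W−1) channels — one
channel per relative offset on the doubled grid.  The pointwise attention at
target position [k,l] and source position [s,t] reads channel
(H−1−k+s, W−1−l+t) of the embedding at [k,l] (0-based; the offset-grid
convention makes the center channel the self-offset).  The "collect" branch
weighs how much position i gathers from each j; the "distribute" branch weighs
how much each j pushes to i.  Aggregating the feature with the sum of the two
attention maps, z_i = (1/N) Σ_j (a^c_{i,j} + a^d_{i,j}) x_j, gives a vector
per position; we reduce it to a scalar by the channel mean and min–max
normalize per sample into Z ∈ [0,1].  A constant raw map (no information)
normalizes to Z ≡ 1 so pooling degrades gracefully to the identity.  The
scalar reduction is a design choice — any bounded, ranking-preserving
reduction would do; the channel mean is the cheapest.

**Radius law.**  With a per-stage *pooling boundary* s ∈ (0,1] and stage width
w, let ς = ln(s·w).  Each position pools over a square window of side 2r−1
with

    r = floor(exp(ς · (1 − Z))),  clamped to r ≥ 1,

so r = 1 at Z = 1 (exact identity) and r = floor(s·w) at Z = 0.  Windows use
reflect padding (mirror without repeating the edge) and stride 1, so feature
maps never change size.  A 1e−9 guard inside the floor keeps exact powers
(e.g. e^{ln 8}) from flooring one short.  Default boundaries are
(1/8, 1/16, 1/8, 1/8) for stages 1–4, the reference model's per-stage optimum.

**Aggregation methods.**  `average` (window mean), `lp` ((mean |x|^p)^{1/p},
p = 2, on absolute values), `mixed` (0.5·max + 0.5·mean, the default), and
`identity` (the no-FP baseline).  For the mean path the gradient of output i
with respect to window element j is exactly η_j/n (η ≡ 1, n the window size),
which the test suite verifies against central finite differences.

**Gradient flow and the floor.**  The floor makes the radius piecewise
constant, so no gradient reaches the importance branch from the segmentation
loss: its parameters are trained only insofar as the shared prior convolution
moves.  This is inherent to the quantized radius law, not an implementation
artifact.  An optional straight-through factor (`fp_importance_grad`)
multiplies the pooled output by exp(ς(1−Z))/detach(exp(ς(1−Z))) — identically
1 in the forward pass — which restores a training signal to the importance
branch at the cost of adding a term to the input gradient that the pure
window-mean contract does not have.  It is off by default; the default path
satisfies the exact η/n gradient, and the parameter-coverage test asserts both
regimes.

**Attention resolution cap.**  The over-complete embedding has
(2H−1)²·H·W entries and is intractable at encoder resolutions of several
hundred pixels.  Importance is therefore computed on the feature bilinearly
resampled to at most `fp_attention_max_hw` (default 32) per side and the
importance map is bilinearly upsampled back — a convex interpolation, so
Z stays in [0,1].

**Ghost encoder.**  Each Ghost layer computes m "intrinsic" maps by a true
convolution (I = X∗f + b) and expands each by cheap 3×3 depthwise transforms
to m·s output channels; the identity transform counts as one of the s, so the
intrinsic maps survive verbatim in the output.  The encoder is one stride-2
stem convolution plus four bottlenecks of four Ghost layers each (strides
1, 2, 2, 1), yielding stage features at 1/2, 1/4, 1/8 and 1/8 of the input
with default widths (16, 24, 40, 80) — the standard Ghost ladder truncated to
four bottlenecks.  Weights are randomly initialized (He); large-scale
pretraining is out of scope.

**nHSIC diversity penalty.**  Cheap transforms alone cannot make intrinsic
maps heterogeneous, so training can penalize their mutual dependence with a
normalized Hilbert–Schmidt independence criterion.  For two representations
on the same s samples, with linear kernels K centered to K̄ = HKH and
regularized to K̃ = K̄(K̄ + ε·s·I)⁻¹ (ε = 1e−5, solved, never inverted),
nHSIC = tr(K̃_i K̃_j) ∈ [0, s].  The loss term averages nHSIC over all
unordered channel pairs (α = 1/#pairs, so the depth of the network does not
change the scale) and enters the objective with weight λ = 0.75.

*Which samples?*  The monitored representations are the intrinsic channels of
the first Ghost layer of each bottleneck, spatially average-pooled to 8×8.
Each channel is treated as a scalar representation over the batch×position
sample axis (s = N·64).  The alternative — batch-only samples with
64-dimensional features — is degenerate at mini-batch sizes like 4: every
centered kernel then equals the same rank-(N−1) projector up to ε, the
penalty is a constant ≈ N−1 and its gradient vanishes.  With scalar
representations the kernels are rank one, K̃ has the closed form
c cᵀ/(‖c‖² + εs), and the pairwise penalty becomes a regularized squared
cosine between centered channels — precisely the CKA-style redundancy the
regularizer is meant to suppress, and verifiably equal to the generic nHSIC
applied to (s, 1) matrices.

**Decoder and assembly.**  The four stage features pass through per-stage FP
modules (independent weights) on the skip connections.  F4 and FP(F3) share
the 1/8 resolution and are fused by concatenation without upsampling; two
bilinear ×2 decoder blocks fuse FP(F2) and FP(F1); a final ×2 block and a 1×1
convolution with sigmoid produce the per-pixel foreground probability
(threshold 0.5 for masks).  Each decoder block is upsample → concatenate →
two 3×3 conv+BN+ReLU — the stock U-Net decoder, the minimal reading of
"concatenated with the decoder output in turn".

**Widths and the parameter footprint.**  Decoder widths and the attention
bottleneck width are not fixed by the architecture description, but the
reference model's parameter footprints constrain them: the full model prints
at 23.23/23.26 MB (4 bytes/parameter; the two reported figures disagree by
0.03 MB) and the identity-skip ablation at 11.98 MB.  The defaults —
decoder ladder (376, 200, 104, 40) and per-stage attention bottleneck widths
(92, 92, 92, 91) — were chosen so the built model reproduces both printed
footprints exactly at print precision: 23.2626 MB full, 11.9800 MB
identity-skip.  Both are configuration options, and the difference between
the two variants equals the summed FP-module parameter count identically.

## Loss and metrics

The objective is L = L_focal + λ·L_nHSIC with λ = 0.75.  The focal term is
the pixel mean of −α_t (1−p_t)^γ log p_t with p_t = p for foreground and 1−p
for background pixels, probabilities clamped to [1e−7, 1−1e−7].  α_t is a
scalar multiplier applied uniformly (so γ = 0, α_t = 1 recovers plain binary
cross-entropy exactly); the hard-pixel focusing is carried by γ.  Defaults
α_t = 0.25, γ = 2 are the canonical focal settings.

Evaluation reports IoU, Dice (DSC), sensitivity, specificity and precision
from exact pixel tallies; DSC = 2·IoU/(1+IoU) holds identically.  Zero
denominators use the empty-vs-empty convention: the metric is 1 when both the
relevant prediction and reference sets are empty and 0 otherwise.  Aggregates
are micro-averages over pooled pixel counts by default; per-image
macro-averaging is a flag.

## Synthetic data

Real inputs are HE-stained tissue tiles where metastases appear as irregular
low-contrast regions.  The generator emulates exactly those properties and no
more: a pink background (mean RGB (225, 190, 215)) with smooth Gaussian
stain texture (σ = 10), 1–3 star-convex blobs per tile with low-order-Fourier
perturbed outlines (radius 8–20 px, perturbation amplitude 0.35), recolored
along a purple direction by a contrast gap of 40 gray levels, and pixel noise
(σ = 6).  Tiles are 96×96 by default (any multiple of 8 works; the real tiles
are 1024×1024), split 40 train / 10 test — the 8:2 ratio of the reference
protocol.  PNG throughout, masks strictly {0, 255}; a fixed seed reproduces
files byte-for-byte.

What this does **not** emulate: nuclear morphology, stain variability across
slides, tissue-boundary artifacts, scanner noise, or truly ambiguous lesion
boundaries.  Passing the end-to-end test therefore shows the pipeline trains,
converges and segments blob-like low-contrast targets — not clinical-grade
performance.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), mini-batch 4.  The reference schedule (300
epochs, freeze for 30, learning rate 1e−4 frozen then 1e−5) presumes a
pretrained encoder; the scaled schedule used for the desk-scale experiments
keeps the structure (20 epochs, freeze 10% of the run) but uses from-scratch
Adam rates (3e−3 frozen phase, 1e−3 main), since 1e−5 cannot train a randomly
initialized encoder in 20 epochs.  During the freeze phase backbone
parameters receive no updates (their tensors are bit-identical across steps);
"iterations" is read as epochs, with `--iteration-unit step` preserving the
other reading.  All randomness (init, data order, augmentation) derives from
one seed; runs are bit-reproducible on one machine.

The end-to-end experiment (also recomputed by `scripts/acceptance.py`) trains
the width-reduced network — stem 8, stages (8, 12, 16, 24), decoder
(48, 32, 24, 16), attention cap 12 — for 20 epochs on the default synthetic
dataset, with and without the nHSIC penalty at the same seed, and compares
the mean off-diagonal CKA among monitored intrinsic channels.  The penalty
reliably roughly quarters the redundancy statistic at these conditions.

## Numerical choices and degenerate inputs

- All network arithmetic is float32; pooling and its oracle comparisons run
  in float64 internally.
- The autodiff engine is a compact reverse-mode implementation over NumPy;
  every primitive's adjoint is covered by central-finite-difference tests
  (tolerance 1e−4 absolute on float64 inputs).
- Reflect padding is mirror-without-edge-repetition everywhere (NumPy
  `reflect` / SciPy `mirror`), asserted identical to the oracle's explicit
  reflection.
- Max-window ties inside mixed pooling take the first argmax (row-major);
  min/max reductions in the engine split gradients equally among ties.
- Importance maps outside [0,1] (impossible through the public path) clamp
  with a warning; radii above the boundary cap raise.
- lp pooling at r = 1 yields |x|, the exact limit of its definition; its
  gradient at an all-zero window is defined as 0.
- Empty-vs-empty metric conventions as above; non-binary masks are rejected
  rather than thresholded silently.

## Known limitations

- The importance branch learns only through the optional straight-through
  factor; with the default exact-gradient contract it is frozen at its random
  initialization, which still yields non-trivial (input-dependent) radius
  maps but not *learned* importance.
- The attention cap trades fidelity of the importance map for tractability;
  at 96×96 tiles with cap 12 the map is computed at 4–8× coarser resolution
  than the stage features.
- Pure-NumPy execution is single-process and CPU-bound; the package targets
  method study at tile scale, not whole-slide throughput.
- The nHSIC penalty saturates if monitored layers have fewer than two
  channels (it returns 0 with a warning).
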