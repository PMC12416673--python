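# Methods

## Problem and model

`hardvessel` segments retinal blood vessels in colour fundus photographs:
given an RGB image and a binary field-of-view (FOV) mask of the camera's
circular aperture, it predicts a per-pixel vessel probability map S(r,c) ∈
[0,1] that is compared with an expert-annotated gold standard G(r,c) ∈ {0,1}
inside the FOV.

The network is a U-shaped encoder–decoder in which

- the encoder stages are **harmonic dense blocks**: within a block, layer k
  receives shortcut connections only from layers k − 2ⁿ for every power of
  two dividing k (layer 0 is the block input), instead of DenseNet's
  all-to-all concatenations.  Layers at higher powers of two are widened
  geometrically — layer k has `even_floor(growth · multiplier^p)` channels
  with p = v₂(k) — to compensate for the pruned shortcuts.  The block
  output concatenates the last layer and all odd-indexed layers; the
  even-indexed activations can be freed as soon as their successors have
  consumed them, which is the memory argument for the harmonic pattern.
- the three deepest encoder scales (1/8, 1/16, 1/32) pass through
  **receptive field blocks (RFB)**: four parallel branches (a 1×1, and
  1×1 → 3×3 convolutions at dilation 1, 3 and 5) concatenated, fused by a
  3×3 convolution and added to a 1×1 shortcut.  The dilated branches widen
  the effective receptive field without extra resolution loss.
- the decoder is a **partial decoder with multiplicative dense
  aggregation**: the shallow 1/4-scale features are discarded entirely;
  coarser maps are bilinearly upsampled (half-pixel convention) and fused
  with finer streams by element-wise multiplication, the fused streams are
  concatenated, transformed by convolution, added to a 1×1 skip projection
  of the finest stream, and projected to single-channel logits at 1/8
  scale, which are bilinearly upsampled to the input resolution and passed
  through a sigmoid.

All convolutions are followed by batch normalisation and ReLU unless noted.
Inputs whose sides are not multiples of 32 are zero-padded internally and
the output cropped back, so the 592×592 (DRIVE-shaped) and 1008×1008
(CHASE-shaped) working sizes run unchanged.

Four ablation variants mirror the architecture study: `baseline` (plain
double-conv stages, bare 1×1 skips), `hard` (harmonic blocks only), `rfb`
(RFB skips only) and `full`.

### Default channel plan

The default "desk" configuration is sized for CPU experiments: stem
3→16→16 (stride 4), per-stage growth rates (10, 16, 18, 24), multiplier
1.7, layers per block (4, 4, 8, 8), stage transitions to (32, 48, 64, 96)
channels, and 16 aggregation channels — about 0.85 M parameters.  A wider
`hardnet68_like_config()` preset exists but no parameter count is asserted
for it: published parameter tables for this family are not derivable
without the exact channel plan, which is not public.

## Loss

Training minimises L = λ₁·L_IoU^w + λ₂·L_BCE^w with λ₁ = λ₂ = 0.5:

- **edge weights**: w(r,c) = 1 + γ·|mean₃₁ₓ₃₁(G)(r,c) − G(r,c)| where the
  mean is over the 31×31 window centred on (r,c) (15 pixels in each
  cardinal direction).  Weights are 1 deep inside vessels and background
  and rise toward 1 + γ at boundaries, focusing the loss on edges.  γ
  defaults to 5 (the proportionality constant is a free parameter; 5 gives
  a 6:1 edge-to-interior emphasis).  At image borders the mean is taken
  over in-bounds pixels only, which keeps w ≡ 1 exact on constant masks; a
  zero-padded policy is available behind `border="zero"`.
- **weighted soft IoU**: L_IoU^w = 1 − Σ w·S·G / Σ w·(S + G − S·G); with
  w ≡ 1 this is the ordinary soft IoU loss.
- **weighted BCE**: L_BCE^w = Σ w·[−G·log S − (1−G)·log(1−S)] / Σ w, with
  S clamped to [ε, 1−ε], ε = 1e−7.

Both terms are 0-minimised at S = G, and the weighted forms place the
weights in both numerator and denominator so that w ≡ 1 recovers the plain
losses exactly.  With deep supervision enabled (off by default) the same
loss is applied to each auxiliary map and summed.

## Training protocol

Adam with β = (0.9, 0.999); learning rate 0.003 for the first 150 epochs,
then 0.0001 (the two-phase schedule is exposed as `lr_switch_epoch`).
Images are min-max normalised to [0,1] and histogram-equalised per RGB
channel (256 bins).  Each training image receives exactly one augmentation
per epoch, drawn uniformly from horizontal flip, vertical flip, contrast
adjustment (deviations from the per-image mean scaled by U[0.8, 1.2]) and
additive Gaussian noise (σ ~ U[0.005, 0.03]); flips are applied to the
masks as well, intensity operations to the image only.  The training set
is split 9:1 into train/validation by sorted id; weights are checkpointed
every 20 epochs ("every 20 iterations" is read as epochs — 20 gradient
steps would be under one epoch on a 20-image dataset) and at every new
best validation loss.  Batch size defaults to 8 at ≤128 px and 2 at full
resolution.  All randomness derives from the config seed, so runs are
reproducible on a fixed machine.

Geometric normalisation is centred zero padding with recorded offsets
(e.g. 584×565 → 592×592 at offsets (4, 13)) and exact cropping back, not
interpolation: padding is the only reading of "resize then crop back to
native resolution" that is lossless for single-pixel vessels.
Interpolation is deliberately not offered as a default.

## Evaluation

Predictions are compared with the gold standard only inside the FOV.
Se = TP/(TP+FN), Sp = TN/(TN+FP), precision = TP/(TP+FP),
F1 = 2·P·R/(P+R), ACC = (TP+TN)/N at a fixed threshold of 0.5, and the
threshold-free AUC from a full ROC sweep (trapezoidal, equal to the
pairwise ranking probability).  Degenerate tables yield NaN plus a flag
rather than an exception.  Dataset aggregation reports both pooled counts
and per-image mean ± std, since either convention appears in the
literature.  A squared macro-averaged F1 (`f1_macro_squared`) is kept as an
alternative aggregation but is not the default: its values are not
commensurable with standard F1 magnitudes.

## Synthetic fundus generator

The simulator exists so the full pipeline is testable without downloading
retinal datasets.  It emulates: a bright circular FOV disc on a dark
background; recursive binary vascular trees rooted on the disc rim (a
segment always continues and bifurcates with probability `branch_prob` at
±30° up to `max_depth` generations, widths decaying multiplicatively from
several-pixel trunks toward single-pixel twigs); vessels rendered darker
than the background, as in fundus photography, over a smooth illumination
gradient with mild red channel dominance; additive Gaussian noise.  Ground
truth is rasterised exactly (a pixel is vessel iff its centre lies within
width/2 of a segment), verified against a brute-force distance transform.
Each sample and each tree draws from an RNG stream derived from
(seed, sample index, tree index), so datasets are bit-reproducible and
adding trees never perturbs existing ones.

What it does **not** emulate: the optic disc and fovea, lesions and
exudates, vessel tortuosity classes, central light reflex, JPEG artefacts,
and inter-observer annotation noise.  Passing the synthetic experiments
therefore demonstrates that the architecture, loss, optimisation and
evaluation machinery are correct and can learn curvilinear structure from
realistic class imbalance — not that the model reaches published
performance on DRIVE/CHASE_DB1, which requires GPU-scale training on the
real images.

Desk-scale experiments use `desk_config()`: 128×128 discs, 4 trees of
depth 4, widths 5 px decaying by 0.8 per generation (≈2 px twigs), vessel
fraction ≈ 8–15% of the FOV — comparable to the class imbalance of real
fundus data.

## Known limitations

The decoder emits logits at 1/8 resolution and upsamples bilinearly ×8.
This is faithful to the partial-decoder design, but it bounds how sharply
thin vessels can be delineated: directly optimising a free 1/8-scale logit
grid against the desk-scale masks (an upper bound no network sharing this
output head can exceed) yields hard Dice ≈ 0.75, and the trained full
model reaches ≈ 0.69 on its training set — the residual errors are a
one-cell-wide halo around every vessel.  Consequently the desk-scale
overfit experiment plateaus near that ceiling rather than approaching 1,
and held-out accuracy saturates around 0.90 with AUC ≈ 0.95: sensitivity
is good (≈ 0.82) but precision suffers (≈ 0.56) because predicted vessels
are blurred wide.  Sharper results would require aggregating the 1/4-scale
stream or a learned upsampling head, both outside the present design.

Other numerical choices: He-normal initialisation; batch-norm ε = 1e−5,
momentum 0.1; bilinear resizing uses the half-pixel (align_corners=False)
convention with edge clamping; ROC computation delegates to scikit-learn's
sweep with `drop_intermediate=False`; Adam ε = 1e−8.  The neural-network
layer is the package's own compact reverse-mode autodiff engine on numpy
(im2col convolutions, separable bilinear resizing, batch normalisation),
kept minimal and verified against finite differences and closed-form
oracles in the test suite.
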