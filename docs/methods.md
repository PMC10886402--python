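# Methods

## Problem and pipeline

The package estimates broiler breast-muscle weight in vivo from a grayscale
radiograph and the bird's live weight. Three stages: (i) a lightweight
encoder–decoder network segments the pectoral muscle into a binary mask;
(ii) 15 shape descriptors are extracted from the mask; (iii) a linear
support-vector regression over recursively selected features (live weight +
descriptors) predicts the weight in grams.

## Segmentation network

**Encoder.** MobileNetV3-Large's inverted-residual stack, truncated: the
classifier head and the final high-channel stages are discarded, and the
network's deepest retained feature map sits at output stride 16 instead of 32
(less aggressive downsampling preserves local detail for a small, smooth
target region). The would-be stride-32 block is retained with its stride
forced to 1 only when the whole model still fits the 1.51 M trainable
parameter budget; with the default decoder widths it does not fit, so the
encoder ends at the last stride-16 block (112 channels) and the assembled
model has 1 120 914 trainable parameters. Grayscale input is replicated to
three channels to reuse the standard stem; the model is always trained from
scratch.

**Decoder.** Taps at strides 4/8/16 (24/40/112 channels) are processed per
tap by:

- *ARM (attention refinement)*: X′ = ReLU(BN(conv3×3(X))), channel gate
  αc = σ(BN(conv1×1(GAP(X′)))), output X′ ⊙ αc. Output widths 32/64/128 at
  strides 4/8/16.
- *CAM (coordinate attention)*: height- and width-pooled descriptors are
  concatenated along the spatial axis, mixed by a shared 1×1 conv + BN +
  hard-swish down to max(8, C/16) channels, split, and restored to C channels
  by two 1×1 convs; sigmoid gates αH (C×H×1) and αW (C×1×W) multiply the
  input. Sigmoid (not ReLU) is used for the gates: a multiplicative
  attention weight must lie in (0, 1), which is also what the
  coordinate-attention design this module follows prescribes.

Fusion proceeds deep-to-shallow: the stride-16 branch is upsampled ×2
(bilinear, half-pixel-aligned) and fused with the stride-8 branch by an
*FFM*: channel concat, X′ = ReLU(BN(conv3×3(·))) to 64 channels, then
out = X′ + X′ ⊙ σ(conv1×1(ReLU(conv1×1(GAP(X′))))). A second FFM (32
channels) fuses with the stride-4 branch; a 1×1 conv produces two-class
logits which are bilinearly upsampled ×4 to input resolution. Since X′ ≥ 0
and the gate is in (0, 1), every FFM output is bounded between X′ and 2X′.

**Numerical engine.** The network runs on `maefnet.nn`, a small numpy
reverse-mode autodiff core written for this package. Convolutions are
evaluated as a shift-and-accumulate over the k² kernel offsets (each step a
contiguous elementwise product for depthwise kernels or a BLAS GEMM for dense
ones); batch norm uses biased batch variance with momentum-0.1 running stats
(ε = 1e-5, unbiased variance stored); bilinear resizing is expressed as two
small interpolation-matrix contractions, making its adjoint exact. All
arithmetic is float32. Gradients of every operation are covered by
central-difference checks in the test suite.

## Training protocol

SGD with momentum 0.9 and weight decay 1e-4, constant learning rate 0.01,
batch size 8, 100 epochs by default. The training objective is mean per-pixel
cross-entropy (probabilities clamped at 1e-12); validation is monitored with
the dice loss 1 − 2|A∩B|/(|A|+|B|) computed on hard argmax predictions
(both-empty counts as loss 0) and with precision/recall/IoU/DSC in percent.
Degenerate-metric conventions: with TP=FP=FN=0 all metrics are 100 (empty
prediction of an empty target is perfect); with TP=0 otherwise, all are 0.
DSC ≡ 2·IoU/(1+IoU) is an algebraic identity and is asserted, not assumed.
Aggregation over a split is micro (pooled pixel counts); per-image and macro
values are also reported. The checkpoint with the best validation IoU is
retained (IoU is the headline metric of this task). Seeded shuffling and
deterministic kernels make two same-seed runs bitwise identical.

## Shape descriptors

All descriptors are computed on the largest 8-connected foreground component
(predicted masks may contain specks). Primitives: pixel count A; convex-hull
pixel count Ca; perimeter P; moment-ellipse major/minor axis lengths
(Mal, Mil); axis-aligned bounding box (H rows × W cols); minimum enclosing
circle diameter D of the boundary-pixel centers. The 15 descriptors are
Ar=√A, Co=√Ca, P, Mal, Mil, H, W, Ra=√(HW), El=Mal/Mil, D, Ed=2√(A/π),
Hcf=P/(2√(πA)), As=H/W, Cu=4A/(πD²), Cl=P²/A.

Two conventions were genuinely open:

- *Perimeter.* The default is the Crofton 4-direction contour-length
  estimate, which is asymptotically unbiased for smooth shapes: a digital
  disk of radius 50 then yields Hcf = 1.004, matching the defining property
  of the Heywood factor (=1 for a circle). The raw boundary-pixel count
  (foreground pixels with a 4-neighbour in the background, image border
  counting as background) is available as `perimeter_mode="boundary_pixels"`;
  it systematically underestimates a circle's perimeter by ≈ 11% (it counts
  ≈ 4√2·r pixels against a true 2πr), which would bias Hcf and Cl for smooth
  regions.
- *Diameter.* "Circumscribed circle" is read as the minimum enclosing circle
  (default); 2× the centroid-to-farthest-boundary distance is available as
  `diameter_mode="centroid_farthest"` — the two differ for asymmetric shapes.

Scale invariance of the dimensionless descriptors (El, As, Hcf, Cu, Cl) holds
within ~5% when the *analytic* shape is rescaled. Integer pixel replication
of a raster is not a pure rescaling — it roughens the boundary into k-pixel
stairs and genuinely raises any perimeter estimate — so invariance is tested
against analytic rescaling.

## Weight model

Candidate predictors: live weight + the 15 descriptors (16 columns).
Features are z-scored per training set; the target stays in grams so the SVR
ε-tube (0.3 g) has physical meaning. The SVR is ε-insensitive with a linear
kernel and C = 10. RFE refits the SVR on the standardized remaining features,
eliminates the feature with the smallest |coefficient| (exact ties broken
toward the later column), records each nested subset's 5-fold CV R²
(seeded shuffled folds; scaler and SVR refit per training fold, so no
leakage), and returns the subset with the maximum CV R² (exact ties toward
the smaller subset). Constant columns are dropped with a warning before
ranking. Exactly collinear candidates — Ed is proportional to Ar by
construction — share the SVR weight, so both outrank noise features and the
selected subset may contain more than one representative of the same signal;
the pipeline stores and reports whatever is selected, with no hard-coding of
an expected subset.

Reported metrics follow the usual definitions: R² = 1 − SS_res/SS_tot,
RMSE = √(mean squared error), MAE, and MRE = mean |relative error| in
percent (undefined and reported as NaN if any actual weight is 0).

## Phantom data

Each phantom is a side² 8-bit image: background ~20, a large jittered body
ellipse at ~140, a muscle blob at +45 above the body, plus Gaussian noise
(σ = 8). The blob is an ellipse (aspect 1.1–1.6, jittered orientation) whose
radius is modulated by 3–5 random cosine harmonics of total amplitude ≤ 15% —
star-convex, hence a single connected component — rescaled until its pixel
count lands in the configured area window (default 5–15% of the frame).
Muscle area fraction is positively coupled to live weight
(0.65·normalized-live-weight + 0.35·uniform), so feature selection faces
correlated candidates as it would on real birds. Live weight is uniform in
1500–3500 g and breast-muscle weight follows
β₀ + β₁·lw + β₂·A + N(0, σ_w) with defaults (50 g, 0.15, 0.008 g/px at the
512 reference side, σ_w = 15 g), placing generated weights roughly in
300–900 g. `PhantomConfig.for_side` rescales β₂ by (512/side)² so the
physical weight law is independent of raster resolution. Generation is
keyed by `default_rng([seed, index])`: bitwise reproducible and
order-independent. Datasets are split 7:2:1 (train/val/test) by a seeded
shuffle.

What the phantoms do *not* emulate: X-ray attenuation physics, skeletal
structure, pose variation, intensity texture inside the muscle, or annotation
noise. Passing tests therefore demonstrate the correctness and convergence
behaviour of the pipeline machinery, not field accuracy on real radiographs.

## Problem sizes used in the test suite

The suite must run on one CPU, so the convergence check trains on 100
phantoms at 192×192 for 30 epochs (batch 8, lr 0.01, SGD 0.9/1e-4 — the
reference protocol with only the canvas and epoch count reduced) and requires
held-out micro-IoU ≥ 90%. Canvas size matters here: the achievable IoU is
capped by the boundary band, roughly 1 − band·perimeter/area with the learned
band ≈ 1 pixel, so the same phantoms plateau near 84% at side 64 and 88% at
side 128 — below the bar for reasons of discretization, not of learning —
while side 192 clears it with a few points of margin (still short of the ~96%
a full-scale run reaches on real data at 512). The weight-recovery check uses
100 noise-free phantoms at side 128, where morphometrics are already
accurate. Miniature runs (side 32, 10 phantoms, 2 epochs) cover
training-loop mechanics and determinism.

## Known limitations

- The numpy engine is single-threaded and ~2 orders of magnitude slower than
  a GPU framework; the 512×512/100-epoch reference protocol is supported but
  slow (eval-mode forward at 512² ≈ 2 s/image on one CPU).
- Dice loss for model selection is computed on hard predictions; soft dice
  is deliberately not implemented.
- The minimum enclosing circle is computed over boundary pixel centers, so D
  is ~1 px smaller than the pixel-extent diameter of a region; all analytic
  checks carry discretization tolerances.
- Checkpoints are .npz archives of raw arrays plus a JSON config; they are
  not interchangeable with any other framework's checkpoints.
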