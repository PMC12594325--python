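# Methods

This note records the model, the choices made where the design was
genuinely open, the numerical conventions, and what the synthetic
benchmark does and does not establish.

## Pipeline

Input is a single-channel image on the normalized [0, 1] intensity scale
(8-bit sources divided by 255; no Hounsfield calibration is attempted —
both intended data sources are JPG/PNG exports). Geometry for an S×S input
(S divisible by 32; S ≥ 64 when texture fusion is enabled):

```
x (B,1,S,S)
  ADWE   x1 = f(x; WL1, WW1, α), x2 = f(x; WL2, WW2, α)      (B,1,S,S)
         Z = σ(conv1×1[x1, x2]);  X* = Z⊙x1 + (1−Z)⊙x2
         F0 = Σ_{k∈{3,5,7}} W_k * X*  (bias-free, same padding) (B,32,S,S)
  stem   conv4×4 /4 + channel LayerNorm                       (B,C,S/4,·)
  stages ConvNeXtV2 blocks (dw7×7 → LN → 1×1 ↑4 → GELU → GRN → 1×1 ↓ → +x),
         2×2 /2 downsampling between stages; dims C·{1,2,4,8}
  MTPF   T = [edge, LBP/255, 8 Gabor channels](X*)            (B,10,S,S)
         T′ = GELU(conv3×3 T)                                 (B,16,S,S)
         at stage-3 output: T′ → bilinear resize → 1×1 projection;
         α = σ(W_α GAP(T′)), β = σ(W_β GAP(F)); F* = α⊙F + β⊙T′
         F_ms = Σ_{s∈{1,2,4}} Upsample(AvgPool_s(F*))
  stage4 → GAP → LayerNorm → linear head → logits
```

Total loss: cross-entropy + λ_hist · histogram term + λ_mmd · MMD term
(defaults 0.1 and 0.01 — small enough not to swamp the classification
objective). Window parameters are hard-clipped into their bounds
(WL ∈ [0.05, 0.95], WW ∈ [0.05, 1.50]) after every optimizer step; the two
windows share one sharpness α (the formula names a single α).

Fusion happens once, at the output of stage 3 of 4, and pyramid pooling is
applied to the fused map before stage 4 consumes it. This placement keeps
the pyramid's {1, 2, 4} grids well defined at the 64×64 test preset
(stage-3 grid 4×4; the stage-4 grid would be 2×2) and matches the reading
that the pooled multi-scale representation is fed back into the
classification backbone.

## Conventions and numerics

* **Windowing** `f(x) = ½(tanh(α(x − WL)/WW) + 1)` is strictly increasing
  with `f(WL) = 0.5`. Openness of the (0, 1) range holds in real
  arithmetic; float64 tanh saturates for |argument| ≳ 19, so tests exercise
  the property below saturation.
* **Soft histogram**: 64 triangular kernels (bandwidth = bin width) over
  (0, 1), renormalized to sum exactly to 1 (triangular kernels lose mass at
  the domain boundary); divergence = squared L2 between normalized
  histograms, which is differentiable, symmetric and zero iff equal. During
  training each histogram is estimated from a seeded subsample of ≤ 8192
  pixels.
* **LBP**: P = 8 neighbours, radius 1; neighbour 0 due east, index
  counter-clockwise; ties (`I_k ≥ I_p`) score 1; circular positions sampled
  bilinearly in lerp form with clamped coordinates (replicate-edge
  behaviour) so that exact ties — constant regions, axis-aligned samples —
  are not flipped by float rounding; axis-aligned offsets are snapped to
  the integer grid for the same reason. The branch is a fixed prior: no
  gradient flows through it.
* **Gabor bank**: wavelengths {4, 8} px × orientations {0, π/4, π/2, 3π/4},
  phase 0 (even-symmetric), σ = 0.56 λ, aspect γ = 0.5, 15×15 kernels;
  responses by convolution with replicate padding. Prior channel order is
  [edge, LBP, Gabor (wavelength-major, then orientation)].
* **MMD**: squared biased V-statistic under an RBF kernel, bandwidth = the
  median pairwise distance of the pooled sample (fallback 1.0 when all
  points coincide), clamped at 0 against float error. The compressed prior
  tensor T′ (16 channels) and the enhanced image X* (1 channel) live in
  different feature spaces, so the constraint compares them as scalar
  samples — activation values of T′ vs intensities of X*, each subsampled
  to ≤ 256 values per batch — the only common space that requires no
  additional learned mapping.
* **AUC**: trapezoidal area over the tie-grouped ROC; numerically identical
  to the Mann–Whitney pairwise-concordance statistic with ½ credit for
  ties. Multiclass metrics use macro (unweighted one-vs-rest) averaging;
  per-class values with empty denominators are NaN, warned about, and
  excluded from macro means. Decline is measured on AUC:
  `decline(σ) = AUC(σ) − AUC(0)`.
* **Cluster indices** are implemented directly (Euclidean): mean silhouette
  (singleton-cluster points score 0), Calinski–Harabasz (∞ for perfectly
  tight clusters), Davies–Bouldin (error on coincident centroids). t-SNE is
  delegated to scikit-learn with a fixed seed.
* **Grad-CAM**: channel weights = spatially averaged gradients of the
  target logit at the named activation; rectified weighted sum, normalized
  to [0, 1] (all-zero maps return zeros with a warning), bilinearly
  upsampled. Default layer is the last backbone stage ('stage4'); any
  recorded intermediate is selectable.

## Training recipe

Defaults mirror the full-scale recipe: AdamW (lr 1e-4, weight decay 1e-5),
batch 32, 100 epochs, cosine annealing, 7:1.5:1.5 stratified splits,
optional label-preserving augmentation (rotation ± 15°, flips, scaling
0.9–1.1, translation, brightness/contrast jitter, gamma). The cosine
schedule uses denominator (epochs − 1) so the final epoch runs at exactly
lr 0. Checkpoint selection keeps the best-validation-accuracy epoch (ties
favour the longer-trained model); no early stopping.

Three knobs exist specifically because desk-scale runs (a few hundred
optimizer steps) behave differently from GPU-scale ones:

* **He (fan-in) initialization** is the library default. With
  0.02-std initial weights the GELUs operate in their linear regime and the
  global-average-pooled features of a fresh network carry almost no
  class signal for small bright lesions; He scaling puts activations at
  O(1) from the first step. (Measured on the phantom task: a linear probe
  on GAP features of an untrained network is near chance at 0.02-std init
  and ≈ 0.86 accurate with He init.)
* **`warmup_epochs`** enables a linear warmup before the cosine decay — the
  standard companion of cosine schedules in the ConvNeXt family. In
  5-epoch runs a full-lr first epoch churns features before the head can
  use them; one warmup epoch at lr/4 removed a persistent plateau.
* **`selection="final"`** keeps the last-epoch model instead of the
  best-validation one. With a 46-image validation split, per-epoch
  accuracy differences are dominated by noise, and best-val selection was
  observed to pick mid-transition epochs that test several points worse.
  Best-val selection remains the default.

The desk-scale smoke configuration used by the test suite and the
acceptance script is: tiny preset, 300 binary phantoms, 5 epochs, batch 2
(more optimizer steps inside the fixed epoch budget), lr 3e-4, 1 warmup
epoch, final-model selection, and a high-density window initialized
sharply at its expected operating point (WL₂ = 0.8, WW₂ = 0.15, α = 6) —
with only a few hundred steps there is no budget to anneal the window into
place. Library defaults keep the gentler inits (WL/WW = 0.25/0.50 and
0.75/0.35, α = 2).

## The synthetic phantom world

Phantoms emulate only the contrasts the modules are designed to exploit:
an anti-aliased parenchymal ellipse (band 0.45–0.65) on a dark background,
plus per class — stone: small disc at 0.88–0.98 (always brighter than any
parenchyma), radius 0.06–0.10 of the image so it covers ≥ 1% of pixels and
a high-percentile intensity statistic always sees it; cyst: homogeneous
disc at 0.15–0.30 with a sharp rim; tumor: irregular region (low-order
radial harmonics) filled with spatially correlated noise, so its interior
variance exceeds a cyst's. Base acquisition noise is Gaussian with
σ = 0.02; robustness-sweep noise is added on the same [0, 1] scale at
σ ∈ {0, 0.01, 0.05, 0.1}. Four-class mixtures default to the real cohort's
proportions (0.408 / 0.298 / 0.111 / 0.183). Everything is deterministic
under (label, params, seed), and drawn lesion radii are clamped to fit
inside the kidney.

What a green synthetic benchmark establishes: that the implementation is
internally consistent, differentiable end to end, trainable, and sensitive
to the intensity/texture structure it claims to model. What it does not
establish: clinical performance. The phantoms have no anatomy beyond one
ellipse, no reconstruction physics, no scanner or protocol variation, and
their class contrasts are far cleaner than real CT. Absolute benchmark
numbers from the source datasets are out of scope here. At the smoke
configuration the held-out accuracy is ≥ 0.90 at the pinned seeds, but an
independent 200-phantom draw puts the same model's skill near 0.8, and
other seeds range from near-chance (occasional collapsed runs — a known
failure mode of very short schedules) to above 0.9. A 44-image test split
has wide confidence bands, which is exactly why the suite also checks
structural properties (loss decrease, noise degradation, decline
conventions) rather than accuracy alone.

## Known limitations

* The autodiff engine is float64 and single-threaded; the full 224×224
  Tiny recipe runs through the same code but is not practical on one CPU.
* The window-parameter recovery experiment isolates the classification
  objective (auxiliary weights 0): the histogram constraint exerts a small
  systematic downward pull on WL₂ that can mask the upward classification
  gradient at very short training lengths.
* LBP and the Gabor bank are fixed priors; no rotation-invariant/uniform
  LBP variants, no learned Gabor parameters, and fusion happens at a single
  site.
* The "residual learning" mentioned only in the source architecture
  diagram has no defining equation and is not implemented.
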