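"""Classifier assembly and training: ADWE -> backbone -> MTPF -> head.

The backbone is a self-contained ConvNeXtV2-style network (depthwise 7x7
convolution, channel LayerNorm, 4x pointwise MLP with GELU and Global
Response Normalization, residual connection), configured to the Tiny recipe
(depths [3, 3, 9, 3], base dim 96) by default and to a desk-scale tiny-test
preset (depths [1, 1, 2, 1], dim 24, 64x64 input) for CI-sized runs.  No
pretrained weights are used.

Pipeline geometry (input size must be divisible by 32):

    input (B, 1, S, S) in [0, 1]
      ADWE: dual windows -> gate -> X* (B, 1, S, S) -> multi-scale conv (B, 32, S, S)
      stem /4 -> stage1 (S/4) -> stage2 (S/8) -> stage3 (S/16)
      MTPF: priors(X*) -> compress -> attention-fuse into stage3 -> pyramid pool
      stage4 (S/32) -> GAP -> LayerNorm -> linear head -> logits (B, K)

Auxiliary losses: a soft-histogram matching term on X* versus the two
views, and a squared MMD between compressed-prior values and X* values;
``total_loss`` combines them with cross-entropy.  The window-parameter
projection (hard clipping to bounds) runs after every optimizer step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, softmax_cross_entropy
from ._nn import AdamW, Conv2d, GRN, DepthwiseConv2d, LayerNormChannels, Linear, \
    Module, cosine_lr
from .adwe import (FusionGate, HistogramConstraintConfig, MultiScaleConv,
                   WindowParams, dual_window_views, gated_fusion,
                   histogram_match_loss, project_window_params)
from .mtpf import (AttentionFusion, GaborBankConfig, MMDConfig, PriorCompressor,
                   attention_fuse, build_prior_stack, mmd_loss, pyramid_pool)
from .synthetic_ct import AugmentSpec, SyntheticDataset, augment

__all__ = ["ModelConfig", "TrainConfig", "Classifier", "build_classifier",
           "total_loss", "train", "save_checkpoint", "load_checkpoint",
           "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    depths: tuple = (3, 3, 9, 3)
    dim: int = 96
    num_classes: int = 2
    input_size: int = 224
    use_adwe: bool = True
    use_mtpf: bool = True
    feature_channels: int = 32     # output channels of the multi-scale conv
    compress_channels: int = 16    # compressed prior channels
    lbp_points: int = 8
    lbp_radius: float = 1.0
    lambda_hist: float = 0.1
    lambda_mmd: float = 0.01
    window_init: dict = field(default_factory=dict)   # overrides for WindowParams
    hist_bins: int = 64
    mmd_max_samples: int = 256

    def __post_init__(self):
        self.depths = tuple(self.depths)
        if len(self.depths) != 4:
            raise ValueError("depths must list four stages")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if self.dim <= 0 or self.input_size <= 0:
            raise ValueError("dims must be positive")
        if self.input_size % 32 != 0:
            raise ValueError("input size must be divisible by 32 (four "
                             "downsampling stages)")
        if self.use_mtpf and self.input_size < 64:
            raise ValueError("pyramid pooling needs a stage-3 grid of >= 4x4 "
                             "(input size >= 64)")
        if self.lambda_hist < 0 or self.lambda_mmd < 0:
            raise ValueError("loss weights must be nonnegative")

    @property
    def dims(self) -> tuple:
        return tuple(self.dim * 2 ** i for i in range(4))

    @classmethod
    def tiny_test(cls, num_classes: int = 2, **kw) -> "ModelConfig":
        """Desk-scale preset: depths [1, 1, 2, 1], dim 24, 64x64 input."""
        kw.setdefault("depths", (1, 1, 2, 1))
        kw.setdefault("dim", 24)
        kw.setdefault("input_size", 64)
        return cls(num_classes=num_classes, **kw)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-5
    warmup_epochs: int = 0     # linear warmup before the cosine decay
    selection: str = "best_val"  # "best_val" | "final" checkpoint choice
    seed: int = 0
    augment_spec: AugmentSpec | None = None
    split_ratio: tuple = (0.70, 0.15, 0.15)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 <= self.warmup_epochs < self.epochs):
            raise ValueError("warmup must be shorter than the run")
        if self.selection not in ("best_val", "final"):
            raise ValueError("selection must be 'best_val' or 'final'")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def lr_at(self, epoch: int) -> float:
        """Linear warmup (if any), then cosine annealing down to 0."""
        if epoch < self.warmup_epochs:
            # epoch-midpoint ramp: a 1-epoch warmup runs at lr/4
            return self.lr * (epoch + 0.5) / (2.0 * self.warmup_epochs)
        return cosine_lr(self.lr, epoch - self.warmup_epochs,
                         self.epochs - self.warmup_epochs)


class ConvNeXtBlock(Module):
    def __init__(self, dim: int, *, rng: np.random.Generator):
        self.dwconv = DepthwiseConv2d(dim, 7, padding=3, rng=rng)
        self.norm = LayerNormChannels(dim)
        self.pw1 = Conv2d(dim, 4 * dim, 1, rng=rng)
        self.grn = GRN(4 * dim)
        self.pw2 = Conv2d(4 * dim, dim, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.pw1(y).gelu()
        y = self.grn(y)
        y = self.pw2(y)
        return x + y


class Downsample(Module):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        self.norm = LayerNormChannels(cin)
        self.conv = Conv2d(cin, cout, 2, stride=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self.norm(x))


class Classifier(Module):
    """Full ADWE + ConvNeXtV2-style backbone + MTPF classifier."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        dims = cfg.dims

        if cfg.use_adwe:
            self.windows = WindowParams.create(**cfg.window_init)
            self.gate = FusionGate(rng=rng)
            self.multiscale = MultiScaleConv(1, cfg.feature_channels, rng=rng)
            stem_in = cfg.feature_channels
        else:
            stem_in = 1
        self.stem_conv = Conv2d(stem_in, dims[0], 4, stride=4, rng=rng)
        self.stem_norm = LayerNormChannels(dims[0])
        self.stages = []
        self.downsamples = []
        for i in range(4):
            if i > 0:
                self.downsamples.append(Downsample(dims[i - 1], dims[i], rng=rng))
            self.stages.append([ConvNeXtBlock(dims[i], rng=rng)
                                for _ in range(cfg.depths[i])])
        if cfg.use_mtpf:
            self.gabor_cfg = GaborBankConfig()
            prior_ch = 2 + self.gabor_cfg.n_channels
            self.compressor = PriorCompressor(prior_ch, cfg.compress_channels, rng=rng)
            self.fusion = AttentionFusion(cfg.compress_channels, dims[2], rng=rng)
        self.head_gamma = Tensor(np.ones(dims[3]), requires_grad=True)
        self.head_beta = Tensor(np.zeros(dims[3]), requires_grad=True)
        self.head = Linear(dims[3], cfg.num_classes, rng=rng)
        self.hist_cfg = HistogramConstraintConfig(n_bins=cfg.hist_bins)

    # ---------------------------------------------------------------- forward
    def forward_with_intermediates(self, x: np.ndarray,
                                   rng: np.random.Generator | None = None,
                                   compute_aux: bool = False):
        """Run the pipeline; returns (logits, aux-loss dict, intermediates)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected a (B, 1, H, W) batch of 1-channel images")
        if x.min() < -1e-6 or x.max() > 1 + 1e-6:
            raise ValueError("input must be normalized to [0, 1]")
        rng = rng if rng is not None else np.random.default_rng(0)
        inter: dict = {}
        aux: dict = {}

        if self.cfg.use_adwe:
            views = dual_window_views(Tensor(x), self.windows)
            fused, zmap = gated_fusion(views, self.gate)
            feats = self.multiscale(fused)
            inter.update(x1=views.x1, x2=views.x2, xstar=fused, gate=zmap,
                         features=feats)
            if compute_aux:
                aux["hist_loss"] = histogram_match_loss(fused, views,
                                                        self.hist_cfg, rng)
            xstar_np = fused.data
            h = feats
        else:
            xstar_np = x
            h = Tensor(x)

        h = self.stem_norm(self.stem_conv(h))
        inter["stem"] = h
        for i in range(4):
            if i > 0:
                h = self.downsamples[i - 1](h)
            for block in self.stages[i]:
                h = block(h)
            inter[f"stage{i + 1}"] = h
            if i == 2 and self.cfg.use_mtpf:
                priors = np.stack([
                    build_prior_stack(xstar_np[b, 0], P=self.cfg.lbp_points,
                                      R=self.cfg.lbp_radius,
                                      cfg=self.gabor_cfg).stacked
                    for b in range(x.shape[0])
                ])  # (B, H, W, Ct)
                tprior = Tensor(np.moveaxis(priors, -1, 1))
                compressed = self.compressor(tprior)
                fused_feat, tproj = attention_fuse(h, compressed, self.fusion)
                pooled = pyramid_pool(fused_feat)
                inter.update(priors=tprior, compressed=compressed,
                             fused=fused_feat, pyramid=pooled)
                if compute_aux:
                    aux["mmd_loss"] = self._mmd(compressed,
                                                inter.get("xstar", Tensor(x)), rng)
                h = pooled

        gap = h.mean(axis=(2, 3))  # (B, C)
        mu = gap.mean(axis=1, keepdims=True)
        xc = gap - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        normed = xc / (var + 1e-6).sqrt()
        logits = self.head(normed * self.head_gamma + self.head_beta)
        inter["gap"] = gap
        return logits, aux, inter

    def _mmd(self, compressed: Tensor, xstar: Tensor,
             rng: np.random.Generator) -> Tensor:
        cap = self.cfg.mmd_max_samples
        a = compressed.reshape(-1, 1)
        b = xstar.reshape(-1, 1)
        if a.shape[0] > cap:
            a = a[np.sort(rng.choice(a.shape[0], cap, replace=False))]
        if b.shape[0] > cap:
            b = b[np.sort(rng.choice(b.shape[0], cap, replace=False))]
        return mmd_loss(a, b, MMDConfig(max_samples=cap))

    def __call__(self, x: np.ndarray) -> Tensor:
        logits, _, _ = self.forward_with_intermediates(x)
        return logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic class probabilities (no aux losses computed)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            logits, _, _ = self.forward_with_intermediates(x[start:start + batch_size])
            z = logits.data - logits.data.max(axis=1, keepdims=True)
            ez = np.exp(z)
            chunks.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(chunks, axis=0)

    def project(self) -> None:
        if self.cfg.use_adwe:
            project_window_params(self.windows)


def build_classifier(cfg: ModelConfig, seed: int = 0) -> Classifier:
    return Classifier(cfg, seed=seed)


def total_loss(logits: Tensor, labels: np.ndarray, aux: dict,
               lambda_hist: float = 0.1, lambda_mmd: float = 0.01) -> Tensor:
    """Cross-entropy plus weighted histogram and MMD auxiliary terms."""
    if lambda_hist < 0 or lambda_mmd < 0:
        raise ValueError("loss weights must be nonnegative")
    loss = softmax_cross_entropy(logits, labels)
    if "hist_loss" in aux and lambda_hist > 0:
        loss = loss + lambda_hist * aux["hist_loss"]
    if "mmd_loss" in aux and lambda_mmd > 0:
        loss = loss + lambda_mmd * aux["mmd_loss"]
    return loss


def _resolve_data(data):
    if isinstance(data, SyntheticDataset):
        return data.subset("train"), data.subset("val")
    if isinstance(data, dict):
        return data["train"], data["val"]
    raise TypeError("data must be a SyntheticDataset or a dict with "
                    "'train'/'val' (X, y) tuples")


def train(model: Classifier, data, cfg: TrainConfig | None = None):
    """AdamW training with cosine-annealed lr and per-step window projection.

    Returns ``(history, checkpoint)``; the checkpoint holds the parameters of
    the best-validation-accuracy epoch plus the resolved configs and seed.
    Fully reproducible under a fixed ``cfg.seed``.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    (x_tr, y_tr), (x_va, y_va) = _resolve_data(data)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty training or validation split")
    x_tr = np.asarray(x_tr, dtype=np.float64)
    x_va = np.asarray(x_va, dtype=np.float64)
    if x_tr.ndim == 3:
        x_tr = x_tr[:, None]
    if x_va.ndim == 3:
        x_va = x_va[:, None]
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = []
    best_acc, best_state = -1.0, None
    n = x_tr.shape[0]
    bs = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        perm = rng.permutation(n)
        losses, correct = [], 0
        aux_sums = {"hist_loss": 0.0, "mmd_loss": 0.0}
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            xb = x_tr[idx]
            if cfg.augment_spec is not None:
                xb = np.stack([augment(im[0], cfg.augment_spec,
                                       seed=int(rng.integers(0, 2 ** 31)))
                               for im in xb])[:, None]
            yb = y_tr[idx]
            logits, aux, _ = model.forward_with_intermediates(
                xb, rng=rng, compute_aux=True)
            loss = total_loss(logits, yb, aux,
                              lambda_hist=model.cfg.lambda_hist,
                              lambda_mmd=model.cfg.lambda_mmd)
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: "
                    f"windows={model.windows.values() if model.cfg.use_adwe else None}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.project()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
            for k in aux_sums:
                if k in aux:
                    aux_sums[k] += float(aux[k].data)
        val_probs = model.predict_proba(x_va, batch_size=max(bs, 32))
        val_pred = val_probs.argmax(axis=1)
        val_acc = float((val_pred == y_va).mean())
        eps = np.finfo(float).tiny
        val_loss = float(-np.log(np.maximum(
            val_probs[np.arange(len(y_va)), y_va], eps)).mean())
        n_batches = max(len(losses), 1)
        row = dict(epoch=epoch, lr=opt.lr,
                   train_loss=float(np.mean(losses)),
                   train_acc=correct / n,
                   val_loss=val_loss, val_acc=val_acc,
                   hist_loss=aux_sums["hist_loss"] / n_batches,
                   mmd_loss=aux_sums["mmd_loss"] / n_batches)
        if model.cfg.use_adwe:
            row.update(model.windows.values())
        history.append(row)
        if val_acc >= best_acc:  # ties favour the longer-trained model
            best_acc = val_acc
            best_state = model.state_dict()
    # "final" keeps the last-epoch parameters: with desk-scale validation
    # splits, per-epoch accuracy is too noisy to select on
    if cfg.selection == "best_val" and best_state is not None:
        model.load_state_dict(best_state)
    checkpoint = dict(state=model.state_dict(),
                      model_config=asdict(model.cfg),
                      train_config={k: (asdict(v) if isinstance(v, AugmentSpec)
                                        else v)
                                    for k, v in asdict(cfg).items()},
                      seed=model.seed, best_val_acc=best_acc)
    return history, checkpoint


def save_checkpoint(path, checkpoint: dict) -> None:
    path = Path(path)
    arrays = {f"param::{k}": v for k, v in checkpoint["state"].items()}
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> Classifier:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"),
                 allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    mc = meta["model_config"]
    mc["depths"] = tuple(mc["depths"])
    cfg = ModelConfig(**mc)
    model = Classifier(cfg, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model


def history_to_csv(history: list, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
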