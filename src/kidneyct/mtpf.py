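"""Multi-Scale Texture Prior Fusion (MTPF).

Lesion classes differ in texture as much as in density: cysts are
homogeneous with a sharp rim, stones are tiny hyperdense foci, tumors are
heterogeneous with irregular margins.  MTPF injects three classical texture
descriptors as fixed (non-trainable) priors computed from the enhanced
image ``X*``:

* a Laplacian edge map (3x3 kernel: center 4, four-neighbours -1, corners 0);
* a Local Binary Pattern (LBP) code map — per pixel, neighbours on a circle
  of radius R are compared to the center, ties counting as 1, and the P
  comparison bits form a code in [0, 2^P - 1];
* a bank of even-symmetric Gabor filters over S wavelengths x O orientations.

The stacked prior tensor is compressed by a learnable 3x3 convolution +
GELU, fused into backbone features through channel attention
(``F* = alpha (.) F + beta (.) T'``), pyramid-pooled over {1, 2, 4} grids,
and regularised by a squared maximum mean discrepancy (MMD) between the
compressed prior values and the enhanced-image intensities.

Channel order of the prior stack (documented contract):
``[edge, lbp/ (2^P - 1), gabor(lambda_0, theta_0), gabor(lambda_0, theta_1),
..., gabor(lambda_{S-1}, theta_{O-1})]`` — wavelength-major, then orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._autodiff import (Tensor, adaptive_avg_pool2d, astensor, resize_bilinear,
                        upsample_nearest)
from ._nn import Conv2d, Linear, Module

__all__ = [
    "LAPLACIAN_KERNEL",
    "GaborBankConfig",
    "TexturePriorStack",
    "MMDConfig",
    "laplacian_edge",
    "lbp_encode",
    "gabor_kernel",
    "gabor_bank_responses",
    "build_prior_stack",
    "PriorCompressor",
    "compress_priors",
    "AttentionFusion",
    "attention_fuse",
    "pyramid_pool",
    "mmd_loss",
]

#: 4-connected Laplacian kernel: zero-sum, so constant regions respond with 0.
LAPLACIAN_KERNEL = np.array([[0.0, -1.0, 0.0],
                             [-1.0, 4.0, -1.0],
                             [0.0, -1.0, 0.0]])


def laplacian_edge(image: np.ndarray) -> np.ndarray:
    """Laplacian edge map with replicate padding (same spatial size)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("laplacian_edge expects a single-channel (H, W) image")
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    # kernel is point-symmetric, so convolution == correlation
    return ndimage.convolve(image, LAPLACIAN_KERNEL, mode="nearest")


def _lbp_offsets(P: int, R: float) -> np.ndarray:
    """Sampling offsets (dy, dx): k=0 due east, proceeding counter-clockwise."""
    k = np.arange(P)
    theta = 2.0 * np.pi * k / P
    dx = R * np.cos(theta)
    dy = -R * np.sin(theta)  # image rows grow downward; CCW means -sin
    off = np.stack([dy, dx], axis=1)
    # snap axis-aligned offsets to the integer grid so exact-value samples
    # (hence the tie rule) are not perturbed by trigonometric rounding
    near = np.abs(off - np.round(off)) < 1e-9
    off[near] = np.round(off[near])
    return off


def lbp_encode(image: np.ndarray, P: int = 8, R: float = 1.0,
               scaled: bool = False) -> np.ndarray:
    """Local Binary Pattern codes with circular bilinear sampling.

    ``code(p) = sum_k 1[I_k >= I_p] * 2^k`` — ties score 1.  Neighbour k=0
    sits at angle 0 (east) and the index increases counter-clockwise.
    Borders use replicate padding.  With ``scaled=True`` the integer codes
    are divided by ``2^P - 1`` for stacking with the other priors.
    """
    image = np.asarray(image, dtype=np.float64)
    if P < 4:
        raise ValueError("P must be at least 4")
    if P > 24:
        raise ValueError("P > 24 would overflow the code range guard")
    if R < 1:
        raise ValueError("R must be at least 1")
    if image.shape[0] <= 2 * R + 1 or image.shape[1] <= 2 * R + 1:
        raise ValueError("image too small for the requested LBP radius")
    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    codes = np.zeros((H, W), dtype=np.int64)
    for k, (dy, dx) in enumerate(_lbp_offsets(P, R)):
        # replicate-edge behaviour via coordinate clamping: an axis-aligned
        # sample collapses to the exact pixel value, keeping ties exact
        sy = np.clip(yy + dy, 0.0, H - 1.0)
        sx = np.clip(xx + dx, 0.0, W - 1.0)
        y0 = np.floor(sy).astype(int)
        x0 = np.floor(sx).astype(int)
        y1 = np.minimum(y0 + 1, H - 1)
        x1 = np.minimum(x0 + 1, W - 1)
        ty = sy - y0
        tx = sx - x0
        # lerp form: exact when the corner values coincide, so a constant
        # image yields exact ties everywhere
        top = image[y0, x0] + (image[y0, x1] - image[y0, x0]) * tx
        bot = image[y1, x0] + (image[y1, x1] - image[y1, x0]) * tx
        sample = top + (bot - top) * ty
        codes += (sample >= image).astype(np.int64) << k
    if scaled:
        return codes / float(2 ** P - 1)
    return codes


@dataclass
class GaborBankConfig:
    """Even-symmetric Gabor bank: S wavelengths x O orientations."""

    wavelengths: tuple = (4.0, 8.0)
    orientations: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    phase: float = 0.0
    sigma_ratio: float = 0.56  # sigma = sigma_ratio * wavelength
    gamma: float = 0.5
    kernel_size: int = 15

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("Gabor kernel size must be odd")
        if any(w <= 0 for w in self.wavelengths):
            raise ValueError("wavelengths must be positive")
        if self.sigma_ratio <= 0:
            raise ValueError("sigma ratio must be positive")

    def sigma(self, wavelength: float) -> float:
        return self.sigma_ratio * wavelength

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths) * len(self.orientations)


def gabor_kernel(cfg: GaborBankConfig, wavelength: float, theta: float) -> np.ndarray:
    """Gabor kernel ``exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x'/lambda + phi)``.

    ``x' = x cos(theta) + y sin(theta)``, ``y' = -x sin(theta) + y cos(theta)``,
    on an integer grid centered at the origin (x rightward, y upward).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if cfg.kernel_size % 2 == 0:
        raise ValueError("Gabor kernel size must be odd")
    half = cfg.kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    x = ax[None, :]           # columns: x grows rightward
    y = ax[::-1, None]        # rows: y grows upward
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    sigma = cfg.sigma(wavelength)
    env = np.exp(-(xp ** 2 + cfg.gamma ** 2 * yp ** 2) / (2.0 * sigma ** 2))
    return env * np.cos(2.0 * np.pi * xp / wavelength + cfg.phase)


def gabor_bank_responses(image: np.ndarray, cfg: GaborBankConfig) -> np.ndarray:
    """Stack of convolution responses (H, W, S*O), wavelength-major order."""
    image = np.asarray(image, dtype=np.float64)
    if cfg.n_channels == 0:
        raise ValueError("empty Gabor bank")
    out = np.empty(image.shape + (cfg.n_channels,))
    i = 0
    for lam in cfg.wavelengths:
        for theta in cfg.orientations:
            kern = gabor_kernel(cfg, lam, theta)
            # the defining form is a convolution; flip the kernel for ndimage.correlate
            out[:, :, i] = ndimage.correlate(image, kern[::-1, ::-1], mode="nearest")
            i += 1
    return out


@dataclass
class TexturePriorStack:
    """Edge + scaled LBP + Gabor responses, concatenated along channels."""

    edge: np.ndarray
    lbp: np.ndarray           # scaled to [0, 1]
    gabor: np.ndarray         # (H, W, S*O)
    stacked: np.ndarray       # (H, W, 2 + S*O)

    @property
    def n_channels(self) -> int:
        return self.stacked.shape[-1]


def build_prior_stack(image: np.ndarray, P: int = 8, R: float = 1.0,
                      cfg: GaborBankConfig | None = None) -> TexturePriorStack:
    """Compute all texture priors of one image and stack them (deterministic)."""
    cfg = cfg if cfg is not None else GaborBankConfig()
    edge = laplacian_edge(image)
    lbp = lbp_encode(image, P=P, R=R, scaled=True)
    gabor = gabor_bank_responses(image, cfg)
    stacked = np.concatenate([edge[:, :, None], lbp[:, :, None], gabor], axis=2)
    return TexturePriorStack(edge=edge, lbp=lbp, gabor=gabor, stacked=stacked)


class PriorCompressor(Module):
    """Learnable compression of the prior tensor: 3x3 conv + GELU."""

    def __init__(self, in_channels: int = 10, out_channels: int = 16,
                 *, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.out_channels = out_channels
        self.conv = Conv2d(in_channels, out_channels, 3, padding=1, bias=True, rng=rng)

    def __call__(self, t: Tensor) -> Tensor:
        return self.conv(t).gelu()


def compress_priors(stack, params: PriorCompressor):
    """Apply the compressor to a prior stack (HWC array or NCHW tensor)."""
    if isinstance(stack, TexturePriorStack):
        stack = stack.stacked
    as_numpy = not isinstance(stack, Tensor)
    t = astensor(stack)
    if t.ndim == 3:  # HWC -> 1CHW
        t = t.transpose(2, 0, 1)
        t = t.reshape(1, *t.shape)
    expected = params.conv.weight.shape[1]
    if t.shape[1] != expected:
        raise ValueError(f"prior stack has {t.shape[1]} channels, compressor expects {expected}")
    out = params(t)
    if as_numpy:
        return out.data
    return out


class AttentionFusion(Module):
    """Channel attention fusing compressed priors into backbone features.

    T' is bilinearly resized to F's spatial grid and 1x1-projected to F's
    channel count; per-channel gates ``alpha = sigmoid(W_a GAP(T'))`` and
    ``beta = sigmoid(W_b GAP(F))`` then weight the two streams:
    ``F* = alpha (.) F + beta (.) T'``.
    """

    def __init__(self, prior_channels: int, feature_channels: int,
                 *, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.feature_channels = feature_channels
        self.projection = Conv2d(prior_channels, feature_channels, 1, bias=True, rng=rng)
        self.w_alpha = Linear(feature_channels, feature_channels, bias=False, rng=rng)
        self.w_beta = Linear(feature_channels, feature_channels, bias=False, rng=rng)

    def __call__(self, features: Tensor, priors: Tensor) -> Tensor:
        f, t = attention_fuse(features, priors, self)
        return f


def attention_fuse(features, priors, params: AttentionFusion):
    """Fuse (B, Cf, H', W') features with (B, Cp, h, w) compressed priors.

    Returns ``(F*, T'_projected)``; gate values live strictly in (0, 1).
    """
    as_numpy = not isinstance(features, Tensor) and not isinstance(priors, Tensor)
    f = astensor(features)
    t = astensor(priors)
    if f.ndim != 4 or t.ndim != 4:
        raise ValueError("attention_fuse expects NCHW tensors")
    if t.shape[2:] != f.shape[2:]:
        t = resize_bilinear(t, f.shape[2:])
    if t.shape[1] != params.projection.weight.shape[1]:
        raise ValueError("prior channel count does not match the fusion projection")
    t = params.projection(t)
    if t.shape != f.shape:
        raise ValueError("internal invariant violated: projected priors mismatch features")
    B, C = f.shape[0], f.shape[1]
    gap_t = t.mean(axis=(2, 3))   # (B, C)
    gap_f = f.mean(axis=(2, 3))
    alpha = params.w_alpha(gap_t).sigmoid().reshape(B, C, 1, 1)
    beta = params.w_beta(gap_f).sigmoid().reshape(B, C, 1, 1)
    fused = alpha * f + beta * t
    if as_numpy:
        return fused.data, t.data
    return fused, t


def pyramid_pool(features):
    """Pyramid pooling: sum of {1, 2, 4}-grid average pools upsampled back.

    Output shape equals input shape; a constant input c maps to 3c.
    """
    as_numpy = not isinstance(features, Tensor)
    f = astensor(features)
    squeezed = False
    if f.ndim == 2:
        f = f.reshape(1, 1, *f.shape)
        squeezed = True
    if f.ndim != 4:
        raise ValueError("pyramid_pool expects (H, W) or (B, C, H, W)")
    H, W = f.shape[2], f.shape[3]
    if H < 4 or W < 4:
        raise ValueError("pyramid pooling needs at least a 4x4 input")
    out = None
    for s in (1, 2, 4):
        term = upsample_nearest(adaptive_avg_pool2d(f, s), (H, W))
        out = term if out is None else out + term
    if squeezed:
        out = out.reshape(H, W)
    return out.data if as_numpy else out


@dataclass
class MMDConfig:
    """Kernel two-sample statistic configuration (biased V-statistic)."""

    kernel: str = "rbf"           # "rbf" | "linear"
    bandwidth: float | None = None  # None => median pairwise-distance heuristic
    max_samples: int = 256

    def __post_init__(self):
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown MMD kernel {self.kernel!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    na = (a * a).sum(axis=1, keepdims=True)          # (n, 1)
    nb = (b * b).sum(axis=1, keepdims=True)          # (m, 1)
    cross = a @ b.transpose(1, 0)
    return (na + nb.transpose(1, 0) - 2.0 * cross).relu()


def mmd_loss(sample_a, sample_b, cfg: MMDConfig | None = None):
    """Squared MMD between two samples of feature vectors (rows).

    RBF kernel with median-distance bandwidth by default; exactly zero for
    identical multisets; clamped at zero against floating-point error.  With
    ``kernel="linear"`` this reduces to ``||mean(a) - mean(b)||^2``.
    """
    cfg = cfg if cfg is not None else MMDConfig()
    as_numpy = not isinstance(sample_a, Tensor) and not isinstance(sample_b, Tensor)
    a = astensor(sample_a)
    b = astensor(sample_b)
    if a.ndim == 1:
        a = a.reshape(-1, 1)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("MMD samples must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"MMD dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if cfg.kernel == "linear":
        d = a.mean(axis=0) - b.mean(axis=0)
        out = (d * d).sum()
    else:
        daa = _pairwise_sq_dists(a, a)
        dbb = _pairwise_sq_dists(b, b)
        dab = _pairwise_sq_dists(a, b)
        if cfg.bandwidth is not None:
            h = cfg.bandwidth
        else:
            pooled = np.sqrt(np.concatenate([daa.data.ravel(), dbb.data.ravel(),
                                             dab.data.ravel()]))
            h = float(np.median(pooled))
            if h <= 0:
                warnings.warn("all points identical; falling back to bandwidth 1.0")
                h = 1.0
        scale = -1.0 / (2.0 * h * h)
        out = ((daa * scale).exp().mean() + (dbb * scale).exp().mean()
               - 2.0 * (dab * scale).exp().mean())
    value = max(float(out.data), 0.0)
    if as_numpy:
        return value
    # keep the graph; clamp only matters for reporting (value >= -eps already)
    return out.relu() if float(out.data) < 0 else out
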