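"""Adaptive Dual-Window Enhancement (ADWE).

CT readers pick a window level (WL) and window width (WW) to map a slice of
the intensity range onto display contrast; a single fixed window cannot
serve soft tissue (parenchyma, cysts) and hyperdense structures (stones) at
once.  This module makes the windowing differentiable and learnable:

* ``window_transform`` — smooth tanh windowing
  ``f(x) = 0.5 * (tanh(alpha * (x - WL) / WW) + 1)``, strictly increasing in
  ``x`` with ``f(WL) = 0.5``;
* two independent (WL, WW) pairs produce a parenchymal and a high-density
  view of the same image;
* a per-pixel sigmoid gate blends the views into a fused image ``X*``;
* a bank of 3/5/7 convolutions extracts multi-scale features from ``X*``;
* a soft-histogram constraint keeps the fused image's intensity statistics
  close to the stated mixture of the two views' statistics.

All operators accept plain ``(H, W)`` / ``(B, 1, H, W)`` NumPy arrays (and
return NumPy) or autodiff ``Tensor`` inputs (and stay differentiable).
Intensities are on the normalized [0, 1] scale throughout; 8-bit sources are
expected to be divided by 255 upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, astensor, concat
from ._nn import Conv2d, Module

__all__ = [
    "WindowParams",
    "ViewPair",
    "HistogramConstraintConfig",
    "window_transform",
    "project_window_params",
    "dual_window_views",
    "FusionGate",
    "gated_fusion",
    "MultiScaleConv",
    "multiscale_features",
    "soft_histogram",
    "histogram_match_loss",
]

# defaults: normalized-intensity windows spanning soft tissue vs hyperdense foci
DEFAULT_INIT = dict(wl1=0.25, ww1=0.50, wl2=0.75, ww2=0.35, alpha=2.0)
DEFAULT_WL_BOUNDS = (0.05, 0.95)
DEFAULT_WW_BOUNDS = (0.05, 1.50)


def _scalar(v) -> float:
    return float(v.data) if isinstance(v, Tensor) else float(v)


@dataclass
class WindowParams:
    """Two learnable (WL, WW) pairs, a shared sharpness alpha, and their bounds."""

    wl1: Tensor
    ww1: Tensor
    wl2: Tensor
    ww2: Tensor
    alpha: Tensor
    wl_bounds: tuple = DEFAULT_WL_BOUNDS
    ww_bounds: tuple = DEFAULT_WW_BOUNDS

    @classmethod
    def create(cls, wl1=None, ww1=None, wl2=None, ww2=None, alpha=None,
               wl_bounds=DEFAULT_WL_BOUNDS, ww_bounds=DEFAULT_WW_BOUNDS):
        a, b = wl_bounds
        c, d = ww_bounds
        if not (b > a):
            raise ValueError(f"inverted window-level bounds [{a}, {b}]")
        if not (d > c > 0):
            raise ValueError(f"invalid window-width bounds [{c}, {d}] (need d > c > 0)")
        init = dict(DEFAULT_INIT)
        for key, val in zip(("wl1", "ww1", "wl2", "ww2", "alpha"),
                            (wl1, ww1, wl2, ww2, alpha)):
            if val is not None:
                init[key] = float(val)
        if init["ww1"] <= 0 or init["ww2"] <= 0:
            raise ValueError("window width must be strictly positive")
        if init["alpha"] <= 0:
            raise ValueError("sharpness alpha must be strictly positive")
        return cls(*(Tensor(init[k], requires_grad=True)
                     for k in ("wl1", "ww1", "wl2", "ww2", "alpha")),
                   wl_bounds=(a, b), ww_bounds=(c, d))

    def parameters(self):
        return [self.wl1, self.ww1, self.wl2, self.ww2, self.alpha]

    def named_parameters(self, prefix: str = ""):
        return [(prefix + k, getattr(self, k))
                for k in ("wl1", "ww1", "wl2", "ww2", "alpha")]

    def values(self) -> dict:
        return {k: _scalar(getattr(self, k))
                for k in ("wl1", "ww1", "wl2", "ww2", "alpha")}


@dataclass
class ViewPair:
    """Parenchymal-window view ``x1`` and high-density-window view ``x2``."""

    x1: object
    x2: object


def window_transform(image, wl, ww, alpha):
    """Differentiable windowing ``0.5 * (tanh(alpha * (x - wl) / ww) + 1)``.

    Strictly increasing in the pixel intensity for ``ww, alpha > 0``; maps the
    window level exactly to 0.5 and saturates smoothly to (0, 1) outside the
    window.  Returns a NumPy array for NumPy input, a ``Tensor`` otherwise.
    """
    if _scalar(ww) <= 0:
        raise ValueError("window width must be strictly positive")
    if _scalar(alpha) <= 0:
        raise ValueError("sharpness alpha must be strictly positive")
    as_numpy = not isinstance(image, Tensor)
    img = astensor(image)
    if not np.all(np.isfinite(img.data)):
        raise ValueError("image contains non-finite values")
    out = ((astensor(alpha) * (img - astensor(wl)) / astensor(ww)).tanh() + 1.0) * 0.5
    return out.data if as_numpy else out


def project_window_params(params: WindowParams) -> WindowParams:
    """Clip both (WL, WW) pairs into their bounds, in place (idempotent).

    Applied after every optimizer step so learned windows remain physically
    reasonable; interior values are untouched.
    """
    a, b = params.wl_bounds
    c, d = params.ww_bounds
    if not (b > a) or not (d > c > 0):
        raise ValueError("invalid projection bounds")
    for t in (params.wl1, params.wl2):
        t.data = np.clip(t.data, a, b)
    for t in (params.ww1, params.ww2):
        t.data = np.clip(t.data, c, d)
    return params


def dual_window_views(image, params: WindowParams) -> ViewPair:
    """Apply the two windows to the same image, yielding complementary views."""
    x1 = window_transform(image, params.wl1, params.ww1, params.alpha)
    x2 = window_transform(image, params.wl2, params.ww2, params.alpha)
    return ViewPair(x1=x1, x2=x2)


class FusionGate(Module):
    """Per-pixel sigmoid gate: 1x1 convolution over the concatenated views."""

    def __init__(self, *, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv = Conv2d(2, 1, 1, bias=True, rng=rng)

    def gate_map(self, x1: Tensor, x2: Tensor) -> Tensor:
        z = self.conv(concat([x1, x2], axis=1))
        return z.sigmoid()


def _as_nchw(x):
    """Lift (H, W) arrays/tensors to (1, 1, H, W); remember how to undo it."""
    t = astensor(x)
    if t.ndim == 2:
        return t.reshape(1, 1, *t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"expected (H, W) or (B, 1, H, W) image, got shape {t.shape}")


def gated_fusion(views: ViewPair, gate: FusionGate):
    """Blend the views with the learned gate: ``X* = Z*x1 + (1-Z)*x2``.

    The fused image is a per-pixel convex combination, so every pixel lies
    between the two views' values at that pixel.
    """
    as_numpy = not isinstance(views.x1, Tensor) and not isinstance(views.x2, Tensor)
    x1, squeezed = _as_nchw(views.x1)
    x2, _ = _as_nchw(views.x2)
    if x1.shape != x2.shape:
        raise ValueError(f"view shapes differ: {x1.shape} vs {x2.shape}")
    z = gate.gate_map(x1, x2)
    fused = z * x1 + (1.0 - z) * x2
    if squeezed:
        fused = fused.reshape(fused.shape[2], fused.shape[3])
        z = z.reshape(z.shape[2], z.shape[3])
    if as_numpy:
        return fused.data, z.data
    return fused, z


class MultiScaleConv(Module):
    """Summed 3/5/7 convolution branches (same padding, bias-free)."""

    KERNEL_SIZES = (3, 5, 7)

    def __init__(self, in_channels: int = 1, out_channels: int = 32,
                 *, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.out_channels = out_channels
        self.branches = [Conv2d(in_channels, out_channels, k, padding=k // 2,
                                bias=False, rng=rng)
                         for k in self.KERNEL_SIZES]

    def __call__(self, x: Tensor) -> Tensor:
        out = self.branches[0](x)
        for br in self.branches[1:]:
            out = out + br(x)
        return out


def multiscale_features(fused, params: MultiScaleConv):
    """Multi-scale feature map ``F = sum_k W_k * X*`` (linear in the input)."""
    as_numpy = not isinstance(fused, Tensor)
    x, squeezed = _as_nchw(fused)
    out = params(x)
    if squeezed:
        out = out.reshape(*out.shape[1:])
    return out.data if as_numpy else out


@dataclass
class HistogramConstraintConfig:
    """Soft-histogram matching constraint weights and binning."""

    lambda1: float = 0.5
    lambda2: float = 0.5
    n_bins: int = 64
    bandwidth: float | None = None  # default: one bin width
    max_pixels: int = 8192  # subsample cap per histogram (gradient estimate)

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be nonnegative")
        if abs(self.lambda1 + self.lambda2 - 1.0) > 1e-6:
            raise ValueError("lambda1 + lambda2 must equal 1")
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")

    @property
    def resolved_bandwidth(self) -> float:
        return self.bandwidth if self.bandwidth is not None else 1.0 / self.n_bins


def soft_histogram(x, n_bins: int = 64, bandwidth: float | None = None):
    """Differentiable normalized histogram over (0, 1) with triangular kernels.

    Each value contributes ``max(0, 1 - |x - c_b| / h)`` to bin ``b`` (center
    ``c_b``, kernel width ``h``); the result is renormalized to sum exactly
    to 1 (triangular kernels lose mass at the domain boundary).
    """
    as_numpy = not isinstance(x, Tensor)
    t = astensor(x).reshape(-1, 1)
    centers = Tensor((np.arange(n_bins) + 0.5) / n_bins)
    h = bandwidth if bandwidth is not None else 1.0 / n_bins
    weights = (1.0 - (t - centers.reshape(1, -1)).abs() * (1.0 / h)).relu()
    hist = weights.sum(axis=0)
    hist = hist / hist.sum()
    return hist.data if as_numpy else hist


def histogram_match_loss(fused, views: ViewPair,
                         cfg: HistogramConstraintConfig | None = None,
                         rng: np.random.Generator | None = None):
    """Squared-L2 divergence between H(X*) and lambda1*H(x1) + lambda2*H(x2).

    Zero exactly when the fused histogram equals the stated mixture; for
    large images a seeded pixel subsample (``cfg.max_pixels``) keeps the
    soft-binning kernel matrix small during training.
    """
    cfg = cfg if cfg is not None else HistogramConstraintConfig()
    as_numpy = not any(isinstance(v, Tensor) for v in (fused, views.x1, views.x2))

    def flat(v):
        t = astensor(v).reshape(-1)
        if t.size > cfg.max_pixels:
            r = rng if rng is not None else np.random.default_rng(0)
            idx = np.sort(r.choice(t.size, size=cfg.max_pixels, replace=False))
            t = t[idx]
        return t

    bw = cfg.resolved_bandwidth
    h_star = soft_histogram(flat(fused), cfg.n_bins, bw)
    h1 = soft_histogram(flat(views.x1), cfg.n_bins, bw)
    h2 = soft_histogram(flat(views.x2), cfg.n_bins, bw)
    h_star, h1, h2 = astensor(h_star), astensor(h1), astensor(h2)
    diff = h_star - (cfg.lambda1 * h1 + cfg.lambda2 * h2)
    loss = (diff * diff).sum()
    return float(loss.data) if as_numpy else loss
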