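"""Seeded synthetic CT phantoms with kidney-lesion class structure.

The generator stands in for the two study settings — a binary stone /
no-stone task and a four-class normal / cyst / stone / tumor task — at the
level of class-conditional intensity and texture contrasts that the model's
modules are designed to exploit:

* **normal** — an anti-aliased parenchymal ellipse on a dark background;
* **cyst** — a homogeneous hypodense disc with a sharp rim inside the kidney;
* **stone** — a small hyperdense focus (brighter than any parenchyma);
* **tumor** — an irregular region (low-order radial harmonics perturb the
  boundary) filled with spatially correlated noise, so its interior variance
  exceeds a cyst's.

All intensities live on the [0, 1] scale; acquisition noise is additive
Gaussian (then clipped), matching the sigma convention of the robustness
sweep.  Everything is deterministic under (label, params, seed).  This is a
test surface for the pipeline, not a clinical simulator: no projection or
reconstruction physics, no anatomy beyond one kidney ellipse per image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_NAMES",
    "BINARY_CLASS_NAMES",
    "FOURCLASS_PROPORTIONS",
    "PhantomParams",
    "PhantomSample",
    "AugmentSpec",
    "SyntheticDataset",
    "generate_phantom",
    "add_noise",
    "rotate",
    "augment",
    "generate_dataset",
    "write_image_folder",
]

CLASS_NAMES = ("normal", "cyst", "stone", "tumor")
BINARY_CLASS_NAMES = ("nostone", "stone")
#: four-class mixture mirroring the published cohort 5077/3709/1377/2283 of 12446
FOURCLASS_PROPORTIONS = (0.408, 0.298, 0.111, 0.183)


@dataclass
class PhantomParams:
    """Geometry and intensity bands of the phantom world (all on [0, 1])."""

    size: int = 64
    background_band: tuple = (0.08, 0.15)
    parenchyma_band: tuple = (0.45, 0.65)
    kidney_axis_a: tuple = (0.28, 0.38)   # semi-axes, fraction of image size
    kidney_axis_b: tuple = (0.18, 0.26)
    cyst_radius: tuple = (0.10, 0.18)     # fraction of image size
    cyst_level: tuple = (0.15, 0.30)
    cyst_edge: float = 0.7                # rim softness in pixels (sharp)
    stone_radius: tuple = (0.06, 0.10)  # >= 1% of pixels, so a high-percentile
                                        # intensity statistic always sees the stone
    stone_level: tuple = (0.88, 0.98)
    tumor_radius: tuple = (0.12, 0.22)
    tumor_boundary_amp: float = 0.30      # radial harmonic amplitude (x radius)
    tumor_noise_scale: float = 2.0        # Gaussian blur of internal noise (px)
    tumor_noise_amp: float = 0.15
    base_noise_sigma: float = 0.02

    def __post_init__(self):
        if self.stone_level[0] <= self.parenchyma_band[1]:
            raise ValueError("stone level must exceed the parenchyma band")
        if self.cyst_level[1] >= self.parenchyma_band[0]:
            raise ValueError("cyst level must lie below the parenchyma band")
        min_axis = self.kidney_axis_b[0]
        for name, rng_ in (("cyst", self.cyst_radius), ("stone", self.stone_radius),
                           ("tumor", self.tumor_radius)):
            if rng_[0] >= min_axis:
                raise ValueError(f"{name} lesion larger than the kidney")


@dataclass
class PhantomSample:
    image: np.ndarray
    label: str
    metadata: dict


def _ellipse_mask(size, cy, cx, a, b, angle, edge=1.0):
    """Anti-aliased ellipse: 1 inside, 0 outside, smooth over ~edge pixels."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / a
    v = (-x * sa + y * ca) / b
    r = np.sqrt(u ** 2 + v ** 2)
    # signed distance approximation scaled to pixels at the boundary
    d = (1.0 - r) * min(a, b)
    return np.clip(0.5 + d / (2.0 * edge), 0.0, 1.0)


def _blob_mask(size, cy, cx, radius, amp, rng, edge=1.0, harmonics=(2, 3, 4, 5)):
    """Irregular star-shaped region: radius perturbed by low-order harmonics."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = yy - cy
    x = xx - cx
    r = np.sqrt(x ** 2 + y ** 2)
    phi = np.arctan2(y, x)
    pert = np.zeros_like(phi)
    for h in harmonics:
        pert += rng.uniform(-1.0, 1.0) * np.cos(h * phi + rng.uniform(0, 2 * np.pi))
    local_radius = radius * (1.0 + amp * pert / len(harmonics))
    d = local_radius - r
    return np.clip(0.5 + d / (2.0 * edge), 0.0, 1.0)


def generate_phantom(label: str, params: PhantomParams | None = None,
                     seed: int = 0) -> PhantomSample:
    """One phantom image; deterministic under (label, params, seed)."""
    params = params if params is not None else PhantomParams()
    valid = set(CLASS_NAMES) | set(BINARY_CLASS_NAMES)
    if label not in valid:
        raise ValueError(f"unknown label {label!r}")
    canonical = "normal" if label == "nostone" else label
    rng = np.random.default_rng(seed)
    size = params.size

    background = rng.uniform(*params.background_band)
    grad = rng.uniform(-0.03, 0.03)
    img = background + grad * (np.linspace(-1, 1, size)[None, :]
                               * np.ones((size, 1)))

    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    a = rng.uniform(*params.kidney_axis_a) * size
    b = rng.uniform(*params.kidney_axis_b) * size
    angle = rng.uniform(0, np.pi)
    parenchyma = rng.uniform(*params.parenchyma_band)
    kidney = _ellipse_mask(size, cy, cx, a, b, angle, edge=1.5)
    img = img * (1 - kidney) + parenchyma * kidney

    meta = dict(label=label, seed=seed, noise_sigma=params.base_noise_sigma,
                kidney=dict(cy=cy, cx=cx, a=a, b=b, angle=angle,
                            parenchyma=parenchyma),
                lesion=None)

    if canonical != "normal":
        # lesion center well inside the kidney
        t = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.35)
        ca, sa = np.cos(angle), np.sin(angle)
        ox, oy = rho * a * np.cos(t), rho * b * np.sin(t)
        lcx = cx + ox * ca - oy * sa
        lcy = cy + ox * sa + oy * ca

        max_r = 0.85 * min(a, b)  # drawn lesions always fit inside the kidney
        if canonical == "cyst":
            radius = min(rng.uniform(*params.cyst_radius) * size, max_r)
            level = rng.uniform(*params.cyst_level)
            mask = _ellipse_mask(size, lcy, lcx, radius, radius, 0.0,
                                 edge=params.cyst_edge)
            img = img * (1 - mask) + level * mask
        elif canonical == "stone":
            radius = min(rng.uniform(*params.stone_radius) * size, max_r)
            level = rng.uniform(*params.stone_level)
            mask = _ellipse_mask(size, lcy, lcx, radius, radius, 0.0, edge=0.7)
            img = img * (1 - mask) + level * mask
        else:  # tumor
            radius = min(rng.uniform(*params.tumor_radius) * size, max_r)
            mask = _blob_mask(size, lcy, lcx, radius,
                              params.tumor_boundary_amp, rng, edge=1.0)
            level = parenchyma + rng.choice([-1.0, 1.0]) * rng.uniform(0.08, 0.18)
            texture = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)),
                                              params.tumor_noise_scale)
            texture = texture / max(texture.std(), 1e-9) * params.tumor_noise_amp
            img = img * (1 - mask) + (level + texture) * mask
        meta["lesion"] = dict(kind=canonical, cy=float(lcy), cx=float(lcx),
                              radius=float(radius), level=float(level))

    img = np.clip(img, 0.0, 1.0)
    img = add_noise(img, params.base_noise_sigma, seed=seed + 1)
    return PhantomSample(image=img, label=label, metadata=meta)


def add_noise(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise of std ``sigma`` on [0, 1], then clip."""
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)


# --------------------------------------------------------------- augmentation

@dataclass
class AugmentSpec:
    """Label-preserving augmentation, applied probabilistically."""

    rotation_deg: float = 15.0
    p_rotate: float = 0.5
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    scale_range: tuple = (0.9, 1.1)
    p_scale: float = 0.5
    translate_frac: float = 0.05
    p_translate: float = 0.5
    brightness: float = 0.1
    p_brightness: float = 0.5
    contrast_range: tuple = (0.9, 1.1)
    p_contrast: float = 0.5
    gamma_range: tuple = (0.8, 1.25)
    p_gamma: float = 0.5

    def __post_init__(self):
        if not (0 <= self.rotation_deg <= 15):
            raise ValueError("rotation must be within +/-15 degrees")
        if not (0.9 <= self.scale_range[0] and self.scale_range[1] <= 1.1):
            raise ValueError("scale range must stay within [0.9, 1.1]")
        for p in (self.p_rotate, self.p_hflip, self.p_vflip, self.p_scale,
                  self.p_translate, self.p_brightness, self.p_contrast,
                  self.p_gamma):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def identity(cls):
        return cls(p_rotate=0, p_hflip=0, p_vflip=0, p_scale=0, p_translate=0,
                   p_brightness=0, p_contrast=0, p_gamma=0)


def _affine(image, matrix, offset):
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="nearest")


def rotate(image: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate about the image center (bilinear, replicate borders)."""
    th = np.deg2rad(degrees)
    c = (np.array(image.shape) - 1) / 2.0
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return _affine(image, rot, c - rot @ c)


def augment(image: np.ndarray, spec: AugmentSpec | None = None,
            seed: int = 0) -> np.ndarray:
    """Apply the configured augmentations with their probabilities (seeded)."""
    spec = spec if spec is not None else AugmentSpec()
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float64).copy()
    if rng.random() < spec.p_rotate:
        out = rotate(out, rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    if rng.random() < spec.p_hflip:
        out = out[:, ::-1].copy()
    if rng.random() < spec.p_vflip:
        out = out[::-1, :].copy()
    if rng.random() < spec.p_scale:
        s = rng.uniform(*spec.scale_range)
        c = (np.array(out.shape) - 1) / 2.0
        mat = np.eye(2) / s
        out = _affine(out, mat, c - mat @ c)
    if rng.random() < spec.p_translate:
        ty, tx = rng.uniform(-spec.translate_frac, spec.translate_frac, 2) \
            * np.array(out.shape)
        out = _affine(out, np.eye(2), np.array([ty, tx]))
    if rng.random() < spec.p_brightness:
        out = out + rng.uniform(-spec.brightness, spec.brightness)
    if rng.random() < spec.p_contrast:
        f = rng.uniform(*spec.contrast_range)
        out = (out - out.mean()) * f + out.mean()
    if rng.random() < spec.p_gamma:
        g = rng.uniform(*spec.gamma_range)
        out = np.clip(out, 0, 1) ** g
    return np.clip(out, 0.0, 1.0)


# ------------------------------------------------------------------ datasets

@dataclass
class SyntheticDataset:
    images: np.ndarray           # (N, H, W)
    labels: np.ndarray           # (N,) int
    class_names: tuple
    metadata: list
    splits: dict                 # name -> index array (train / val / test)

    def subset(self, split: str):
        idx = self.splits[split]
        return self.images[idx], self.labels[idx]


def _largest_remainder(n: int, fractions) -> np.ndarray:
    raw = np.asarray(fractions, dtype=np.float64) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


SPLIT_FRACTIONS = (0.70, 0.15, 0.15)  # train : val : test = 7 : 1.5 : 1.5


def generate_dataset(n: int, proportions=None, params: PhantomParams | None = None,
                     seed: int = 0, task_mode: str = "binary") -> SyntheticDataset:
    """Stratified phantom dataset with a 7:1.5:1.5 train/val/test split."""
    if task_mode == "binary":
        class_names = BINARY_CLASS_NAMES
        proportions = proportions if proportions is not None else (0.5, 0.5)
    elif task_mode == "fourclass":
        class_names = CLASS_NAMES
        proportions = proportions if proportions is not None else FOURCLASS_PROPORTIONS
    else:
        raise ValueError(f"unknown task mode {task_mode!r}")
    proportions = np.asarray(proportions, dtype=np.float64)
    if len(proportions) != len(class_names):
        raise ValueError("one proportion per class required")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n < len(class_names):
        raise ValueError("n smaller than the number of classes")
    params = params if params is not None else PhantomParams()

    counts = _largest_remainder(n, proportions)
    rng = np.random.default_rng(seed)
    images, labels, metadata = [], [], []
    split_idx = {"train": [], "val": [], "test": []}
    pos = 0
    for ci, (cname, count) in enumerate(zip(class_names, counts)):
        for _ in range(count):
            sample = generate_phantom(cname, params,
                                      seed=int(rng.integers(0, 2 ** 31)))
            images.append(sample.image)
            labels.append(ci)
            metadata.append(sample.metadata)
        class_positions = np.arange(pos, pos + count)
        perm = rng.permutation(class_positions)
        n_tr, n_va, n_te = _largest_remainder(count, SPLIT_FRACTIONS)
        split_idx["train"].extend(perm[:n_tr])
        split_idx["val"].extend(perm[n_tr:n_tr + n_va])
        split_idx["test"].extend(perm[n_tr + n_va:])
        pos += count
    return SyntheticDataset(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=int),
        class_names=class_names,
        metadata=metadata,
        splits={k: np.sort(np.asarray(v, dtype=int)) for k, v in split_idx.items()},
    )


def write_image_folder(dataset: SyntheticDataset, out_dir) -> Path:
    """Write class-per-directory PNGs plus a metadata CSV (CLI-consumable)."""
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    for split, idx in dataset.splits.items():
        for i in idx:
            cname = dataset.class_names[dataset.labels[i]]
            cdir = out_dir / split / cname
            cdir.mkdir(parents=True, exist_ok=True)
            path = cdir / f"{i:06d}.png"
            arr = np.clip(dataset.images[i] * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
            meta = dataset.metadata[i]
            lesion = meta.get("lesion") or {}
            rows.append(dict(path=str(path.relative_to(out_dir)), split=split,
                             label=cname, seed=meta["seed"],
                             noise_sigma=meta["noise_sigma"],
                             lesion_kind=lesion.get("kind", ""),
                             lesion_radius=lesion.get("radius", ""),
                             lesion_level=lesion.get("level", "")))
    rows.sort(key=lambda r: r["path"])
    with open(out_dir / "metadata.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return out_dir
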