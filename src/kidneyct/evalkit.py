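"""Evaluation toolkit: classification metrics, robustness sweeps, cluster
quality, Grad-CAM and 2-D embeddings.

Conventions (recorded in every report):

* binary tasks report positive-class (label 1) precision/recall/F1 and the
  ROC AUC of the positive-class score;
* multiclass tasks use **macro** (unweighted one-vs-rest) averaging for
  precision, recall, F1 and AUC; per-class values with an empty denominator
  are undefined (NaN) and excluded from the macro mean with a warning;
* AUC is the trapezoidal area under the ROC over all score thresholds; with
  the half-credit tie convention it equals the Mann-Whitney pairwise
  concordance statistic exactly;
* the robustness "decline" at noise level sigma is AUC(sigma) - AUC(0), so
  the sigma = 0 row is exactly 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._autodiff import Tensor, resize_bilinear
from .synthetic_ct import add_noise

__all__ = [
    "ConfusionCounts", "MetricsReport", "RobustnessTable",
    "confusion_matrix", "accuracy", "precision_recall", "f1", "auc",
    "evaluate", "robustness_sweep", "cluster_metrics", "grad_cam", "embed_2d",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. single-class AUC)."""


@dataclass
class ConfusionCounts:
    """K x K counts; rows are true classes, columns predicted classes."""

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    def binary_counts(self, positive: int = 1) -> dict:
        """One-vs-rest TP/TN/FP/FN for the given positive class."""
        m = self.matrix
        tp = int(m[positive, positive])
        fn = int(m[positive].sum() - tp)
        fp = int(m[:, positive].sum() - tp)
        tn = int(m.sum() - tp - fn - fp)
        return dict(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError(f"labels outside [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return ConfusionCounts(matrix=m)


def accuracy(counts: ConfusionCounts) -> float:
    """Trace over total: the overall fraction of correct predictions."""
    if counts.n == 0:
        raise UndefinedMetricError("accuracy undefined on an empty sample")
    return float(np.trace(counts.matrix)) / counts.n


def precision_recall(counts: ConfusionCounts, class_k: int = 1):
    """One-vs-rest precision and recall; NaN (with warning) on 0/0."""
    c = counts.binary_counts(positive=class_k)
    if c["tp"] + c["fp"] == 0:
        warnings.warn(f"precision undefined for class {class_k} (no predictions)")
        precision = np.nan
    else:
        precision = c["tp"] / (c["tp"] + c["fp"])
    if c["tp"] + c["fn"] == 0:
        warnings.warn(f"recall undefined for class {class_k} (no positives)")
        recall = np.nan
    else:
        recall = c["tp"] / (c["tp"] + c["fn"])
    return precision, recall


def f1(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R); defined as 0 (with warning) if P = R = 0."""
    if np.isnan(precision) or np.isnan(recall):
        return np.nan
    if precision == 0 and recall == 0:
        warnings.warn("F1 defined as 0 for precision = recall = 0")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auc(scores, labels) -> float:
    """Trapezoidal ROC area; equals pairwise concordance with half tie credit."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = pos[order]
    # group tied scores: cumulative TP/FP only at the last index of each group
    boundary = np.r_[s[1:] != s[:-1], True]
    ctp = np.cumsum(y)[boundary]
    cfp = np.cumsum(~y)[boundary]
    tpr = np.r_[0.0, ctp / n_pos]
    fpr = np.r_[0.0, cfp / n_neg]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricsReport:
    """Accuracy plus precision / recall / F1 / AUC with the stated averaging."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    averaging: str                      # "binary" or "macro"
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            return None if (isinstance(v, float) and np.isnan(v)) else v
        return dict(accuracy=self.accuracy, precision=clean(self.precision),
                    recall=clean(self.recall), f1=clean(self.f1),
                    auc=clean(self.auc), averaging=self.averaging,
                    per_class={k: {kk: clean(vv) for kk, vv in v.items()}
                               for k, v in self.per_class.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _nanmean(values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    if not vals:
        return np.nan
    return float(np.mean(vals))


def report_from_scores(probs: np.ndarray, labels: np.ndarray) -> tuple:
    """Build (MetricsReport, ConfusionCounts) from class probabilities."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    K = probs.shape[1]
    preds = probs.argmax(axis=1)
    counts = confusion_matrix(labels, preds, K)
    acc = accuracy(counts)
    per_class = {}
    for k in range(K):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(counts, k)
            fk = f1(p, r)
            try:
                ak = auc(probs[:, k], (labels == k).astype(int))
            except UndefinedMetricError:
                ak = np.nan
        per_class[k] = dict(precision=p, recall=r, f1=fk, auc=ak)
    if K == 2:
        pc = per_class[1]
        report = MetricsReport(accuracy=acc, precision=pc["precision"],
                               recall=pc["recall"], f1=pc["f1"], auc=pc["auc"],
                               averaging="binary", per_class=per_class)
    else:
        report = MetricsReport(
            accuracy=acc,
            precision=_nanmean([v["precision"] for v in per_class.values()]),
            recall=_nanmean([v["recall"] for v in per_class.values()]),
            f1=_nanmean([v["f1"] for v in per_class.values()]),
            auc=_nanmean([v["auc"] for v in per_class.values()]),
            averaging="macro", per_class=per_class)
    return report, counts


def evaluate(model, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> tuple:
    """Deterministic evaluation; returns (MetricsReport, ConfusionCounts)."""
    probs = model.predict_proba(images, batch_size=batch_size)
    return report_from_scores(probs, labels)


@dataclass
class RobustnessTable:
    """Per-sigma metric rows plus the AUC-decline statistic."""

    rows: list  # list of dicts: sigma, report, decline

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["sigma", "accuracy", "precision", "recall",
                             "f1", "auc", "decline"])
            for row in self.rows:
                rep = row["report"]
                writer.writerow([row["sigma"], rep.accuracy, rep.precision,
                                 rep.recall, rep.f1, rep.auc, row["decline"]])


def robustness_sweep(model, images: np.ndarray, labels: np.ndarray,
                     sigma_list=(0.0, 0.01, 0.05, 0.1),
                     seed: int = 0) -> RobustnessTable:
    """Evaluate a fixed model on noise-corrupted copies of the test set.

    ``decline = AUC(sigma) - AUC(0)``; the sigma = 0 row is exactly 0.  Noise
    is seeded per sigma so the sweep is reproducible.
    """
    sigma_list = list(sigma_list)
    if 0.0 not in sigma_list:
        raise ValueError("sigma_list must include 0 (the reference row)")
    images = np.asarray(images, dtype=np.float64)
    rows = []
    auc0 = None
    for i, sigma in enumerate(sigma_list):
        if sigma == 0:
            noisy = images
        else:
            noisy = np.stack([add_noise(im, sigma, seed=seed * 1009 + i * 131 + j)
                              for j, im in enumerate(images)])
        report, _ = evaluate(model, noisy, labels)
        rows.append(dict(sigma=sigma, report=report, decline=None))
        if sigma == 0:
            auc0 = report.auc
    for row in rows:
        row["decline"] = 0.0 if row["sigma"] == 0 else row["report"].auc - auc0
    return RobustnessTable(rows=rows)


# ------------------------------------------------------------------ clusters

def cluster_metrics(embeddings: np.ndarray, labels: np.ndarray) -> tuple:
    """(silhouette, Calinski-Harabasz, Davies-Bouldin), Euclidean.

    Direct implementations of the three standard formulas; singleton-cluster
    points get silhouette 0.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    classes, y = np.unique(y, return_inverse=True)
    K, n = len(classes), len(y)
    if K < 2:
        raise UndefinedMetricError("cluster metrics need at least 2 clusters")
    if n < 3:
        raise UndefinedMetricError("cluster metrics need at least 3 points")

    D = cdist(X, X)
    sil = np.zeros(n)
    for i in range(n):
        same = (y == y[i])
        n_same = same.sum()
        if n_same < 2:
            sil[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, y == k].mean() for k in range(K) if k != y[i])
        sil[i] = (b - a) / max(a, b)
    silhouette = float(sil.mean())

    centroids = np.stack([X[y == k].mean(axis=0) for k in range(K)])
    overall = X.mean(axis=0)
    counts = np.bincount(y, minlength=K)
    between = float((counts * ((centroids - overall) ** 2).sum(axis=1)).sum())
    within = float(sum(((X[y == k] - centroids[k]) ** 2).sum() for k in range(K)))
    if within == 0:
        ch = np.inf  # perfectly tight clusters
    else:
        ch = (between / (K - 1)) / (within / (n - K))

    spread = np.array([np.linalg.norm(X[y == k] - centroids[k], axis=1).mean()
                       for k in range(K)])
    cd = cdist(centroids, centroids)
    if np.any(cd[~np.eye(K, dtype=bool)] == 0):
        raise UndefinedMetricError("Davies-Bouldin undefined for coincident "
                                   "centroids")
    db_terms = []
    for i in range(K):
        db_terms.append(max((spread[i] + spread[j]) / cd[i, j]
                            for j in range(K) if j != i))
    db = float(np.mean(db_terms))
    return silhouette, float(ch), db


# ------------------------------------------------------------------ grad-cam

def grad_cam(model, image: np.ndarray, target_class: int,
             layer_name: str = "stage4") -> np.ndarray:
    """Gradient-weighted class activation map, normalized to [0, 1].

    ``model`` must expose ``forward_with_intermediates`` returning
    ``(logits, aux, {name: Tensor})``; the named activation's channels are
    weighted by their spatially averaged gradients, summed, rectified, and
    bilinearly upsampled to the input size.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None, None]
    elif image.ndim == 3:
        image = image[None]
    logits, _, inter = model.forward_with_intermediates(image)
    if layer_name not in inter:
        raise ValueError(f"unknown layer {layer_name!r}; available: "
                         f"{sorted(inter)}")
    act = inter[layer_name]
    if act.ndim != 4:
        raise ValueError(f"layer {layer_name!r} is not spatial")
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    if act.grad is None:
        raise ValueError(f"no gradient reaches layer {layer_name!r}")
    weights = act.grad.mean(axis=(2, 3), keepdims=True)      # (1, C, 1, 1)
    cam = np.maximum((weights * act.data).sum(axis=1, keepdims=True), 0.0)
    cam = resize_bilinear(Tensor(cam), image.shape[2:]).data[0, 0]
    peak = cam.max()
    if peak <= 0:
        warnings.warn("Grad-CAM map is identically zero")
        return np.zeros_like(cam)
    return cam / peak


def embed_2d(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """t-SNE embedding to 2-D (delegated to scikit-learn), seeded."""
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 points to embed")
    perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, init="pca",
                perplexity=perplexity)
    return tsne.fit_transform(X)
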