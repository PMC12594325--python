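"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle is a deliberately naive reimplementation (explicit loops,
closed forms, exhaustive enumeration) kept separate from the library code it
checks.
"""

import numpy as np


def auc_concordance(scores, labels) -> float:
    """Pairwise Mann-Whitney statistic with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def lbp_reference(image, P=8, R=1.0):
    """Per-pixel bit enumeration with scalar bilinear sampling.

    Convention under test: neighbour k=0 due east, counter-clockwise order
    (rows grow downward, so dy = -R sin(theta)), ties (I_k >= I_p) score 1,
    replicate padding at borders.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape

    def sample(y, x):
        y = min(max(y, 0.0), H - 1.0)
        x = min(max(x, 0.0), W - 1.0)
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
        ty, tx = y - y0, x - x0
        top = image[y0, x0] + (image[y0, x1] - image[y0, x0]) * tx
        bot = image[y1, x0] + (image[y1, x1] - image[y1, x0]) * tx
        return top + (bot - top) * ty

    codes = np.zeros((H, W), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            code = 0
            for k in range(P):
                theta = 2 * np.pi * k / P
                dy, dx = -R * np.sin(theta), R * np.cos(theta)
                if abs(dy - round(dy)) < 1e-9:
                    dy = round(dy)
                if abs(dx - round(dx)) < 1e-9:
                    dx = round(dx)
                val = sample(r + dy, c + dx)
                if val >= image[r, c]:
                    code |= 1 << k
            codes[r, c] = code
    return codes


def mmd_double_sum(a, b, bandwidth) -> float:
    """Explicit double-sum biased V-statistic over RBF Gram entries."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))

    def k(u, v):
        return np.exp(-np.sum((u - v) ** 2) / (2.0 * bandwidth ** 2))

    n, m = len(a), len(b)
    kaa = sum(k(a[i], a[j]) for i in range(n) for j in range(n)) / n ** 2
    kbb = sum(k(b[i], b[j]) for i in range(m) for j in range(m)) / m ** 2
    kab = sum(k(a[i], b[j]) for i in range(n) for j in range(m)) / (n * m)
    return kaa + kbb - 2 * kab


def silhouette_bruteforce(X, y) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes = np.unique(y)
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(np.mean([np.linalg.norm(X[i] - X[j])
                         for j in range(n) if y[j] == k])
                for k in classes if k != y[i])
        s[i] = (b - a) / max(a, b)
    return float(np.mean(s))


def calinski_harabasz_bruteforce(X, y) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n, K = len(y), len(classes)
    overall = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for k in classes:
        pts = X[y == k]
        c = pts.mean(axis=0)
        between += len(pts) * np.sum((c - overall) ** 2)
        within += sum(np.sum((p - c) ** 2) for p in pts)
    return (between / (K - 1)) / (within / (n - K))


def davies_bouldin_bruteforce(X, y) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    cents = {k: X[y == k].mean(axis=0) for k in classes}
    spread = {k: np.mean([np.linalg.norm(p - cents[k]) for p in X[y == k]])
              for k in classes}
    terms = []
    for i in classes:
        terms.append(max((spread[i] + spread[j])
                         / np.linalg.norm(cents[i] - cents[j])
                         for j in classes if j != i))
    return float(np.mean(terms))
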