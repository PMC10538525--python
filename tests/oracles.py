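"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the library routines they are checking:
flood-fill labeling vs scipy labeling, gift-wrapping + shoelace vs Qhull,
textbook statistics formulas vs the stats module, dense resampling vs
analytic arclengths.
"""

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """BFS flood-fill connected-component labeling."""
    mask = np.asarray(mask, bool)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for r0, c0 in np.argwhere(mask):
        if labels[r0, c0]:
            continue
        nxt += 1
        q = deque([(r0, c0)])
        labels[r0, c0] = nxt
        while q:
            r, c = q.popleft()
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                        and mask[rr, cc] and not labels[rr, cc]):
                    labels[rr, cc] = nxt
                    q.append((rr, cc))
    return labels


def partition_signature(labels: np.ndarray) -> set:
    """Label-order-independent signature of a labeling: frozensets of pixels."""
    sig = {}
    for r, c in np.argwhere(labels > 0):
        sig.setdefault(labels[r, c], set()).add((r, c))
    return {frozenset(v) for v in sig.values()}


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Jarvis-march convex hull (counterclockwise vertex list)."""
    pts = np.unique(np.asarray(points, float), axis=0)
    if len(pts) < 3:
        return pts
    hull = []
    start = min(range(len(pts)), key=lambda i: (pts[i][0], pts[i][1]))
    p = start
    while True:
        hull.append(pts[p])
        q = (p + 1) % len(pts)
        for r in range(len(pts)):
            u, v = pts[q] - pts[p], pts[r] - pts[p]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[r] - pts[p])
                             > np.linalg.norm(pts[q] - pts[p])):
                q = r
        p = q
        if p == start:
            break
    return np.array(hull)


def shoelace_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def r_squared_oracle(x, y) -> float:
    """R^2 from the raw covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov**2 / (x.var() * y.var()))


def paired_t_oracle(x, y):
    """Textbook paired t statistic and two-sided p-value."""
    from scipy.special import stdtr

    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * (1.0 - stdtr(n - 1, abs(t)))
    return float(t), float(p)


def resampled_arclength(vertices: np.ndarray, factor: int = 50) -> float:
    """Arclength after dense linear resampling of a polyline."""
    v = np.asarray(vertices, float)
    total = 0.0
    for a, b in zip(v[:-1], v[1:]):
        ts = np.linspace(0.0, 1.0, factor + 1)[:, None]
        fine = a + ts * (b - a)
        total += np.linalg.norm(np.diff(fine, axis=0), axis=1).sum()
    return float(total)
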