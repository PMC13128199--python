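"""Independent brute-force oracles.

Deliberately naive implementations (explicit loops, textbook formulas) kept
separate from the package so each metric can be checked against a second,
independently derived computation.
"""

import math

import numpy as np


def brute_clip(x, y, center, radius):
    """Indices of points with horizontal distance <= radius, by direct scan."""
    keep = []
    for i in range(len(x)):
        if math.hypot(x[i] - center[0], y[i] - center[1]) <= radius:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def brute_idw_ground(px, py, gx, gy, gz, k, p):
    """IDW ground elevation at one point from its k nearest ground returns."""
    d = [math.hypot(px - gx[i], py - gy[i]) for i in range(len(gx))]
    order = np.argsort(d, kind="stable")[: min(k, len(gx))]
    if d[order[0]] < 1e-12:
        return gz[order[0]]
    wsum, zsum = 0.0, 0.0
    for i in order:
        w = d[i] ** (-p)
        wsum += w
        zsum += w * gz[i]
    return zsum / wsum


def brute_band_pct(heights_veg, n_total, lo, hi):
    """Percentage of all returns that are vegetation with lo <= h < hi."""
    if n_total == 0:
        return float("nan")
    n = sum(1 for h in heights_veg if lo <= h < hi)
    return 100.0 * n / n_total


def brute_quantile(values, q):
    """Linear-interpolation quantile between order statistics."""
    v = sorted(values)
    n = len(v)
    if n == 1:
        return v[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def brute_sd(values, ddof=0):
    n = len(values)
    mu = sum(values) / n
    return math.sqrt(sum((v - mu) ** 2 for v in values) / (n - ddof))


def brute_edge_length(forest, in_plot):
    """4-neighbour scan counting forest / in-plot-non-forest shared sides."""
    ny, nx = forest.shape
    edges = 0
    for j in range(ny):
        for i in range(nx):
            if not forest[j, i]:
                continue
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                jj, ii = j + dj, i + di
                if 0 <= jj < ny and 0 <= ii < nx:
                    if in_plot[jj, ii] and not forest[jj, ii]:
                        edges += 1
    return float(edges)


def brute_nearest_water(point, water_mask, x0, y0):
    """Exhaustive scan for the nearest water-cell centre."""
    ny, nx = water_mask.shape
    best = float("inf")
    for j in range(ny):
        for i in range(nx):
            if water_mask[j, i]:
                d = math.hypot(point[0] - (x0 + i + 0.5), point[1] - (y0 + j + 0.5))
                best = min(best, d)
    return best


def gift_wrap_area(points):
    """Convex-hull area via gift wrapping + shoelace formula."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, float), axis=0)]
    n = len(pts)
    if n < 3:
        return float("nan")
    start = min(pts)
    hull = [start]
    current = start
    while True:
        cand = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (cand[0] - current[0]) * (p[1] - current[1]) - (
                cand[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and math.hypot(p[0] - current[0], p[1] - current[1])
                > math.hypot(cand[0] - current[0], cand[1] - current[1])
            ):
                cand = p
        current = cand
        if current == start:
            break
        hull.append(current)
    if len(hull) < 3:
        return float("nan")
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def rank_average(values):
    """Average ranks (1-based) with ties shared."""
    v = np.asarray(values, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(a, b):
    """Rank both vectors, then Pearson on the ranks."""
    ra, rb = rank_average(a), rank_average(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / math.sqrt((ra @ ra) * (rb @ rb)))


def brute_pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float((a @ b) / math.sqrt((a @ a) * (b @ b)))


def brute_auc(scores_pres, scores_bg):
    """Exhaustive pair count: wins + half-ties."""
    wins = 0.0
    for sp in scores_pres:
        for sb in scores_bg:
            if sp > sb:
                wins += 1.0
            elif sp == sb:
                wins += 0.5
    return wins / (len(scores_pres) * len(scores_bg))


def brute_tss(scores_pres, scores_bg):
    """Exhaustive threshold sweep (unique values, midpoints, one above max)."""
    allv = sorted(set(list(scores_pres) + list(scores_bg)))
    thresholds = list(allv)
    thresholds += [(a + b) / 2 for a, b in zip(allv[:-1], allv[1:])]
    thresholds.append(allv[-1] + 1.0)
    best = -1.0
    for t in thresholds:
        sens = sum(1 for s in scores_pres if s >= t) / len(scores_pres)
        spec = sum(1 for s in scores_bg if s < t) / len(scores_bg)
        best = max(best, sens + spec - 1.0)
    return best
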