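"""Independent brute-force reference implementations used to check the
package. These deliberately share no code with the package internals."""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_qvalues_bruteforce(p):
    """q_i = min over j with p_j >= p_i of min(1, p_j * m / rank_j)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, min(1.0, p[i] * m / rank))
        q[i] = running_min
    return q


def rankdata_average(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x, y):
    """Pearson correlation of average ranks."""
    rx = rankdata_average(list(x))
    ry = rankdata_average(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def mannwhitney_u(a, b):
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_perm_p_two_sided(a, b):
    """Two-sided exact permutation p for the MW effect |U - n_a n_b / 2|."""
    pooled = list(a) + list(b)
    na = len(a)
    mu = na * len(b) / 2
    obs = abs(mannwhitney_u(a, b) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if abs(mannwhitney_u(ga, gb) - mu) >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def proximity_count_bruteforce(immune_xy, dcis_xy, radius):
    """Number of immune cells whose nearest DCIS cell is within radius."""
    count = 0
    for ix, iy in immune_xy:
        for dx, dy in dcis_xy:
            if math.hypot(ix - dx, iy - dy) <= radius:
                count += 1
                break
    return count


def complete_linkage_heights(points):
    """Merge heights of naive complete-linkage agglomeration (Euclidean)."""
    clusters = [[i] for i in range(len(points))]
    pts = [np.asarray(p, float) for p in points]

    def cdist(ca, cb):
        return max(np.linalg.norm(pts[i] - pts[j]) for i in ca for j in cb)

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def point_in_polygon_raycast(x, y, polygon):
    """Even-odd ray casting for a simple polygon (list of (x, y) vertices)."""
    inside = False
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xint:
                inside = not inside
    return inside


def kruskal_h_bruteforce(groups):
    """Tie-corrected Kruskal–Wallis H."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rankdata_average(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start : start + len(g)])
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = 1.0 - sum(c**3 - c for c in counts.values()) / (n**3 - n)
    return h / tie
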