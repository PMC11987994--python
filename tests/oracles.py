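"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive and self-contained: explicit pixel
enumeration, a monotone-chain convex hull, hand-rolled mid-ranks.  None of it
imports the code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# blob geometry

def bf_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Monotone-chain convex hull, CCW in a y-down coordinate frame."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def bf_mask_corner_points(mask: np.ndarray) -> list[tuple[float, float]]:
    """All four unit-square corners of every foreground pixel, as (u, v)."""
    pts = []
    vv, uu = np.nonzero(mask)
    for u, v in zip(uu.tolist(), vv.tolist()):
        pts += [(u, v), (u + 1, v), (u, v + 1), (u + 1, v + 1)]
    return pts


def bf_polygon_area(verts: list[tuple[float, float]]) -> float:
    """Shoelace area (absolute)."""
    n = len(verts)
    s = 0.0
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def bf_polygon_centroid(verts: list[tuple[float, float]]) -> tuple[float, float]:
    n = len(verts)
    a = 0.0
    cx = cy = 0.0
    for i in range(n):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % n]
        w = x0 * y1 - x1 * y0
        a += w
        cx += (x0 + x1) * w
        cy += (y0 + y1) * w
    if abs(a) < 1e-12:
        xs = [p[0] for p in verts]
        ys = [p[1] for p in verts]
        return sum(xs) / n, sum(ys) / n
    return cx / (3.0 * a), cy / (3.0 * a)


def bf_largest_component(mask: np.ndarray, min_area: float):
    """Largest 8-connected component by flood fill; ties by bbox origin.

    Returns a boolean mask of the winning component or None.
    """
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    best = None
    best_key = None
    for sv in range(h):
        for su in range(w):
            if not mask[sv, su] or seen[sv, su]:
                continue
            stack = [(sv, su)]
            seen[sv, su] = True
            comp = []
            while stack:
                v, u = stack.pop()
                comp.append((v, u))
                for dv in (-1, 0, 1):
                    for du in (-1, 0, 1):
                        nv, nu = v + dv, u + du
                        if (0 <= nv < h and 0 <= nu < w and mask[nv, nu]
                                and not seen[nv, nu]):
                            seen[nv, nu] = True
                            stack.append((nv, nu))
            if len(comp) < min_area:
                continue
            v0 = min(c[0] for c in comp)
            u0 = min(c[1] for c in comp)
            key = (-len(comp), v0, u0)
            if best_key is None or key < best_key:
                best_key = key
                m = np.zeros_like(mask, dtype=bool)
                for v, u in comp:
                    m[v, u] = True
                best = m
    return best


def bf_dilate(mask: np.ndarray, structure: np.ndarray,
              iterations: int) -> np.ndarray:
    """Morphological dilation by explicit neighbourhood enumeration."""
    sh, sw = structure.shape
    cv, cu = sh // 2, sw // 2
    out = mask.astype(bool).copy()
    h, w = mask.shape
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        for v in range(h):
            for u in range(w):
                if not out[v, u]:
                    continue
                for dv in range(sh):
                    for du in range(sw):
                        if structure[dv, du]:
                            nv, nu = v + dv - cv, u + du - cu
                            if 0 <= nv < h and 0 <= nu < w:
                                nxt[nv, nu] = True
        out = nxt
    return out


# ---------------------------------------------------------------------------
# rank statistics

def bf_midranks(values: list[float]) -> list[float]:
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0   # mean of 1-based ranks i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def bf_tie_sum(values: list[float]) -> float:
    t = 0.0
    for v in set(values):
        c = values.count(v)
        t += c ** 3 - c
    return t


def bf_kruskal_h(groups: list[list[float]]) -> float:
    """Tie-corrected Kruskal–Wallis H from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = bf_midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start:start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - bf_tie_sum(pooled) / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def bf_dunn_z(groups: list[list[float]]) -> np.ndarray:
    """Dunn pairwise z-statistics from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = bf_midranks(pooled)
    mean_r = []
    start = 0
    for g in groups:
        mean_r.append(sum(ranks[start:start + len(g)]) / len(g))
        start += len(g)
    var_base = n * (n + 1) / 12.0 - bf_tie_sum(pooled) / (12.0 * (n - 1))
    k = len(groups)
    z = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            se = math.sqrt(var_base * (1 / len(groups[i]) + 1 / len(groups[j])))
            z[i, j] = (mean_r[i] - mean_r[j]) / se if se > 0 else 0.0
    return z
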