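"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit Python loops, flood
fills, textbook formulas) and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
RUN_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def brute_glcm_matrix(levels, mask, offset, n_bins):
    """Symmetric normalized co-occurrence matrix by explicit pair enumeration."""
    h, w = levels.shape
    dy, dx = offset
    counts = np.zeros((n_bins, n_bins))
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w and mask[y2, x2]:
                a, b = levels[y, x] - 1, levels[y2, x2] - 1
                counts[a, b] += 1
                counts[b, a] += 1
    total = counts.sum()
    return counts / total if total else None


def brute_glcm_features(p):
    n = p.shape[0]
    mu = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    sigma2 = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(n) for j in range(n))
    feats = {
        "contrast": 0.0, "dissimilarity": 0.0, "homogeneity": 0.0,
        "asm": 0.0, "joint_entropy": 0.0, "cluster_shade": 0.0,
        "cluster_prominence": 0.0,
    }
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            gi, gj = i + 1, j + 1
            feats["contrast"] += pij * (gi - gj) ** 2
            feats["dissimilarity"] += pij * abs(gi - gj)
            feats["homogeneity"] += pij / (1 + abs(gi - gj))
            feats["asm"] += pij**2
            if pij > 0:
                feats["joint_entropy"] -= pij * math.log2(pij)
            feats["cluster_shade"] += pij * (gi + gj - 2 * mu) ** 3
            feats["cluster_prominence"] += pij * (gi + gj - 2 * mu) ** 4
            corr_num += pij * (gi - mu) * (gj - mu)
    feats["correlation"] = corr_num / sigma2 if sigma2 > 0 else 1.0
    return feats


def brute_runs(levels, mask, direction):
    """All maximal runs (gray, length) along one direction, scanning each
    line pixel by pixel."""
    h, w = levels.shape
    dy, dx = direction
    starts = []
    for y in range(h):
        for x in range(w):
            py, px = y - dy, x - dx
            if 0 <= py < h and 0 <= px < w:
                continue  # not a line start
            starts.append((y, x))
    runs = []
    for y0, x0 in starts:
        y, x = y0, x0
        cur_val, cur_len = None, 0
        while 0 <= y < h and 0 <= x < w:
            val = levels[y, x] if mask[y, x] else 0
            if val == cur_val and val != 0:
                cur_len += 1
            else:
                if cur_val not in (None, 0):
                    runs.append((cur_val, cur_len))
                cur_val, cur_len = val, 1
            y, x = y + dy, x + dx
        if cur_val not in (None, 0):
            runs.append((cur_val, cur_len))
    return runs


def brute_glrlm_features(runs, n_pixels):
    nr = len(runs)
    feats = {
        "sre": sum(1.0 / l**2 for _, l in runs) / nr,
        "lre": sum(l**2 for _, l in runs) / nr,
        "run_percentage": nr / n_pixels,
        "lglre": sum(1.0 / g**2 for g, _ in runs) / nr,
        "hglre": sum(g**2 for g, _ in runs) / nr,
    }
    by_gray: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for g, l in runs:
        by_gray[g] = by_gray.get(g, 0) + 1
        by_len[l] = by_len.get(l, 0) + 1
    feats["gln"] = sum(c**2 for c in by_gray.values()) / nr
    feats["rln"] = sum(c**2 for c in by_len.values()) / nr
    return feats


def brute_zones(levels, mask):
    """8-connected equal-level zones by explicit flood fill."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            g = levels[y, x]
            stack, size = [(y, x)], 0
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and mask[ny, nx] and not seen[ny, nx]
                            and levels[ny, nx] == g
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            zones.append((g, size))
    return zones


def brute_glszm_features(zones, n_pixels):
    nz = len(zones)
    feats = {
        "sze": sum(1.0 / s**2 for _, s in zones) / nz,
        "lze": sum(s**2 for _, s in zones) / nz,
        "zone_percentage": nz / n_pixels,
    }
    by_gray: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for g, s in zones:
        by_gray[g] = by_gray.get(g, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    feats["gln"] = sum(c**2 for c in by_gray.values()) / nz
    feats["szn"] = sum(c**2 for c in by_size.values()) / nz
    return feats


def anova_icc(table):
    """Textbook one-way ANOVA ICC(1,1) for a complete subjects x repeats table."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    ss_between = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_within = sum(
        (table[i, j] - row_means[i]) ** 2 for i in range(n) for j in range(k)
    )
    ms_between = ss_between / (n - 1)
    ms_within = ss_within / (n * (k - 1))
    return (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)


def random_roi(seed, shape=(6, 6), n_levels=4):
    """A small random discretized ROI with an irregular random mask."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    while mask.sum() < 4:
        mask = rng.random(shape) < 0.8
    levels[~mask] = 0
    return levels, mask
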