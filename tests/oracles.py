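"""Independent brute-force oracles used to cross-check the package.

Everything here is written from the definitional contracts only and stays
deliberately naive (sorting, enumeration, dense convolution, definitional
prominence scans) so it shares no code path with the implementations it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def background_fit_lowest_fraction(x, y, fraction):
    """Sort intensities, take the lowest ceil(fraction*n), solve the normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = math.ceil(fraction * x.size)
    order = sorted(range(x.size), key=lambda i: (y[i], i))[:m]
    xs = x[order]
    ys = y[order]
    # normal equations of OLS y = a*x + b, solved by hand
    sx, sy = xs.sum(), ys.sum()
    sxx, sxy = (xs * xs).sum(), (xs * ys).sum()
    n = len(order)
    denom = n * sxx - sx * sx
    a = (n * sxy - sx * sy) / denom
    b = (sy - a * sx) / n
    return a, b


def definitional_prominence(y, i):
    """Topographic prominence of sample i: height above the higher of the two
    key saddles (minimum between the peak and the nearest higher terrain on
    each side, or the profile end)."""
    h = y[i]
    bases = []
    for direction in (-1, 1):
        j = i
        lowest = h
        base = None
        while True:
            j += direction
            if j < 0 or j >= len(y):
                base = lowest
                break
            lowest = min(lowest, y[j])
            if y[j] > h:
                base = lowest
                break
        bases.append(base)
    return h - max(bases)


def local_maxima_with_plateaus(y):
    """Indices of local maxima; a flat run higher than both neighbours counts
    once, at its midpoint (floor of the run centre)."""
    out = []
    i = 1
    n = len(y)
    while i < n - 1:
        if y[i] <= y[i - 1]:
            i += 1
            continue
        j = i
        while j < n - 1 and y[j + 1] == y[i]:
            j += 1
        if j < n - 1 and y[j + 1] < y[i]:
            out.append((i + j) // 2)
        i = j + 1
    return out


def brute_force_peaks(x, y, min_prominence, min_separation):
    """Exhaustive scan applying the peak definitions sample by sample."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    ymax = y.max()
    if ymax <= 0:
        return np.empty(0)
    candidates = [
        i for i in local_maxima_with_plateaus(y)
        if definitional_prominence(y, i) >= min_prominence * ymax
    ]
    kept = []
    for i in sorted(candidates, key=lambda i: (-y[i], x[i])):
        if all(abs(x[i] - x[j]) >= min_separation for j in kept):
            kept.append(i)
    return x[sorted(kept)]


def naive_gaussian_smooth(y, sigma):
    """Dense truncated-Gaussian convolution with symmetric (reflect) padding."""
    radius = int(4.0 * sigma + 0.5)
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(np.asarray(y, float), radius, mode="symmetric")
    out = np.empty(len(y))
    for i in range(len(y)):
        out[i] = np.dot(padded[i:i + 2 * radius + 1], kernel[::-1])
    return out


def mann_whitney_enumeration(a, b):
    """Exact two-sided p by enumerating every group assignment; U by pairwise
    comparison counts (ties count 1/2), no ranks involved."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for va in group_a:
            for vb in group_b:
                if va > vb:
                    u += 1.0
                elif va == vb:
                    u += 0.5
        return u

    u_obs = u_of(a, b)
    mu = n1 * len(b) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    count = total = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, n1):
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx if i not in chosen]
        total += 1
        if abs(u_of(ga, gb) - mu) >= dev:
            count += 1
    return u_obs, count / total


def exhaustive_span_pairs(zdisc, partner, max_span):
    """Step-by-step re-derivation of the span pairing: at each step pick the
    globally smallest remaining feasible (z-disc side, nearest partner)
    candidate, consuming partners."""
    zdisc = sorted(map(float, zdisc))
    partner = sorted(map(float, partner))
    candidates = []
    for i, p in enumerate(zdisc):
        lefts = [q for q in partner if q < p]
        rights = [q for q in partner if q > p]
        for q in ([max(lefts)] if lefts else []) + ([min(rights)] if rights else []):
            d = abs(q - p)
            if d <= max_span:
                candidates.append((d, i, partner.index(q)))
    spans = []
    taken = set()
    while True:
        feasible = [c for c in candidates if c[2] not in taken]
        if not feasible:
            break
        best = min(feasible, key=lambda c: (c[0], c[1], c[2]))
        taken.add(best[2])
        candidates.remove(best)
        spans.append(best[0])
    return spans
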