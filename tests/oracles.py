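"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops, exact
rational arithmetic, direct formulas) and never calls the code paths it
checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def brute_membrane(cell_mask: np.ndarray, width: int) -> set[tuple[int, int]]:
    """Cell pixels with Chebyshev distance <= width to any non-cell pixel."""
    H, W = cell_mask.shape
    out = set()
    for r in range(H):
        for c in range(W):
            if not cell_mask[r, c]:
                continue
            near_bg = False
            for dr in range(-width, width + 1):
                for dc in range(-width, width + 1):
                    rr, cc = r + dr, c + dc
                    if rr < 0 or cc < 0 or rr >= H or cc >= W or not cell_mask[rr, cc]:
                        near_bg = True
            if near_bg:
                out.add((r, c))
    return out


def brute_dilate_l1(pixels: set[tuple[int, int]], radius: int) -> set[tuple[int, int]]:
    out = set()
    for r, c in pixels:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if abs(dr) + abs(dc) <= radius:
                    out.add((r + dr, c + dc))
    return out


def brute_sigma(channel: np.ndarray, contact: set, noncontact: set) -> float:
    """log2 ratio of pixel-set means via explicit loops."""
    cs = sum(channel[r, c] for r, c in contact) / len(contact)
    ns = sum(channel[r, c] for r, c in noncontact) / len(noncontact)
    return math.log2(cs / ns)


def pairwise_distance_histogram(
    ref_xy: np.ndarray, tgt_xy: np.ndarray, bin_um: float, n_bins: int,
    exclude_same_index: bool = False,
) -> np.ndarray:
    """O(n^2) per-bin pair counts, summed over reference points."""
    counts = np.zeros(n_bins)
    for i, (rx, ry) in enumerate(ref_xy):
        for j, (tx, ty) in enumerate(tgt_xy):
            if exclude_same_index and i == j:
                continue
            d = math.hypot(rx - tx, ry - ty)
            b = int(d // bin_um)
            if b < n_bins:
                counts[b] += 1
    return counts


def direct_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = math.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def direct_paired_t(x, y):
    """Two-sided paired t-test from the textbook formula."""
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), df=n - 1)
    return t, p


def direct_one_sample_t(values):
    """One-sided (greater) one-sample t-test vs 0."""
    from scipy.stats import t as tdist

    v = np.asarray(values, float)
    n = v.size
    t = v.mean() / (v.std(ddof=1) / math.sqrt(n))
    return t, tdist.sf(t, df=n - 1)


def exhaustive_multiotsu(levels, counts, n_classes):
    """All optimal threshold triples by exact rational enumeration.

    Maximizes the between-class variance equivalent (sum of
    class_weight * class_mean^2) with Fraction arithmetic over every way of
    cutting the sorted distinct levels into ``n_classes`` contiguous groups.
    Returns (best objective, set of threshold tuples) with thresholds as
    midpoints between bordering levels.
    """
    levels = [Fraction(str(v)) if not isinstance(v, int) else Fraction(v) for v in levels]
    counts = [Fraction(int(c)) for c in counts]
    n = len(levels)
    pref_w = [Fraction(0)]
    pref_s = [Fraction(0)]
    for w, v in zip(counts, levels):
        pref_w.append(pref_w[-1] + w)
        pref_s.append(pref_s[-1] + w * v)

    def f(i, j):
        w = pref_w[j] - pref_w[i]
        s = pref_s[j] - pref_s[i]
        return s * s / w

    best = None
    best_cuts = []
    for cuts in combinations(range(1, n), n_classes - 1):
        bounds = (0, *cuts, n)
        obj = sum(f(bounds[k], bounds[k + 1]) for k in range(n_classes))
        if best is None or obj > best:
            best = obj
            best_cuts = [cuts]
        elif obj == best:
            best_cuts.append(cuts)
    thresholds = {
        tuple(
            (levels[c - 1] + levels[c]) / 2 for c in cuts
        )
        for cuts in best_cuts
    }
    return best, thresholds


def exhaustive_two_means(values):
    """Best split of sorted values into two clusters by scanning; returns
    (threshold, positives mask) like the implementation contract."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    best_sse, best_k = None, None
    for k in range(1, n):
        lo, hi = v[:k], v[k:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_k = sse, k
    thr = v[best_k:].mean()
    return thr, np.asarray(values, float) >= thr


def gaussian_impulse_response(shape, pos, sigma=1.0):
    """Blur of a unit impulse via direct convolution with a sampled,
    renormalized Gaussian kernel (matching reflective boundary handling is
    avoided by keeping the impulse away from borders)."""
    rad = int(4 * sigma + 0.5)
    ax = np.arange(-rad, rad + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 = k1 / k1.sum()
    kern = np.outer(k1, k1)
    out = np.zeros(shape)
    r0, c0 = pos
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                out[rr, cc] = kern[dr + rad, dc + rad]
    return out


def upper_quartile_mean_sorted(values):
    """Sort-and-average reference for the upper-quartile mean statistic."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    # linear-interpolation 75th percentile
    h = 0.75 * (n - 1)
    lo = int(math.floor(h))
    q75 = v[lo] + (h - lo) * (v[min(lo + 1, n - 1)] - v[lo])
    tail = [x for x in v if x >= q75]
    return sum(tail) / len(tail)
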