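"""Independent brute-force reference implementations used only by the
tests.  Everything here is written with plain loops and textbook
formulas, deliberately sharing no code with the package."""

import itertools
import math


def shannon_bf(row):
    total = sum(row)
    h = 0.0
    for v in row:
        if v > 0:
            p = v / total
            h -= p * math.log(p)
    return h


def bray_curtis_bf(u, v):
    num = sum(abs(a - b) for a, b in zip(u, v))
    den = sum(a + b for a, b in zip(u, v))
    return num / den


def ranks_bf(values):
    """Average ranks (ties share the mean of their rank range)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h_bf(values, groups):
    """Tie-corrected Kruskal-Wallis H via explicit rank arithmetic."""
    n = len(values)
    ranks = ranks_bf(values)
    labels = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    h = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        rbar = sum(ranks[i] for i in idx) / len(idx)
        h += len(idx) * (rbar - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    tie_counts = {}
    for v in values:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in tie_counts.values()) / (n ** 3 - n)
    if correction == 0.0:
        return 0.0
    return h / correction


def ols_bf(x, y):
    """Slope/intercept/R^2 through the correlation-coefficient route."""
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sxx = sum((a - xm) ** 2 for a in x)
    syy = sum((b - ym) ** 2 for b in y)
    sxy = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return r2, slope, intercept


def permanova_ss_bf(d, labels):
    """(SS_total, SS_within, SS_between) by explicit pair loops on a
    square distance matrix (list of lists)."""
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d[idx[a]][idx[b]] ** 2
        ss_within += s / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def pav_bf(y):
    """O(n^2) pooled-adjacent-violators isotonic regression (nondecreasing,
    equal weights) via repeated block merging."""
    blocks = [[v, 1] for v in y]  # [mean, size]
    changed = True
    while changed:
        changed = False
        out = []
        for b in blocks:
            out.append(list(b))
            while len(out) > 1 and out[-2][0] > out[-1][0]:
                m2, s2 = out.pop()
                m1, s1 = out.pop()
                out.append([(m1 * s1 + m2 * s2) / (s1 + s2), s1 + s2])
                changed = True
        blocks = out
    fit = []
    for m, s in blocks:
        fit.extend([m] * s)
    return fit


def two_group_assignments(n, k):
    """All distinct ways to pick which k of n samples form group A."""
    return list(itertools.combinations(range(n), k))
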