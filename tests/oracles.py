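"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and explicit
enumeration, deliberately sharing no code with the package's vectorized
paths.
"""

from __future__ import annotations

import math


def brute_relieff_weights(X, y, k, miss_weighting="class_prior"):
    """ReliefF weights by exhaustive neighbour enumeration (plain loops).

    X: list of rows (floats, may contain NaN); y: list of int labels.
    Returns a list of per-feature weights with the same definition the
    package documents: range-normalized diffs, missing -> per-feature
    mean observed diff, k nearest hits / k nearest misses per class with
    (distance, index) ordering, miss classes weighted uniformly or by
    prior P(c)/(1 - P(class(x))), accumulated over every instance and
    divided by n.
    """
    n = len(X)
    M = len(X[0])
    classes = sorted(set(y))
    counts = {c: sum(1 for v in y if v == c) for c in classes}
    priors = {c: counts[c] / n for c in classes}

    widths = []
    mean_diffs = []
    for f in range(M):
        vals = [X[i][f] for i in range(n) if not math.isnan(X[i][f])]
        w = (max(vals) - min(vals)) if vals else 0.0
        widths.append(w)
        if w <= 0 or len(vals) < 2:
            mean_diffs.append(0.0)
        else:
            tot, cnt = 0.0, 0
            for a in range(len(vals)):
                for b in range(a + 1, len(vals)):
                    tot += abs(vals[a] - vals[b]) / w
                    cnt += 1
            mean_diffs.append(tot / cnt)

    def diff(i, j, f):
        if widths[f] <= 0:
            return 0.0
        a, b = X[i][f], X[j][f]
        if math.isnan(a) or math.isnan(b):
            return mean_diffs[f]
        return abs(a - b) / widths[f]

    def dist(i, j):
        return sum(diff(i, j, f) for f in range(M))

    W = [0.0] * M
    for i in range(n):
        ci = y[i]
        hit_pool = [j for j in range(n) if j != i and y[j] == ci]
        hits = sorted(hit_pool, key=lambda j: (dist(i, j), j))[: min(k, len(hit_pool))]
        hit_avg = [sum(diff(i, j, f) for j in hits) / len(hits) for f in range(M)]
        miss_term = [0.0] * M
        for c in classes:
            if c == ci:
                continue
            pool = [j for j in range(n) if y[j] == c]
            near = sorted(pool, key=lambda j: (dist(i, j), j))[: min(k, len(pool))]
            avg = [sum(diff(i, j, f) for j in near) / len(near) for f in range(M)]
            if miss_weighting == "class_prior":
                w_c = priors[c] / (1.0 - priors[ci])
            else:
                w_c = 1.0 / (len(classes) - 1)
            for f in range(M):
                miss_term[f] += w_c * avg[f]
        for f in range(M):
            W[f] += (miss_term[f] - hit_avg[f]) / n
    return W


def brute_prf1(true, pred, classes):
    """Per-class precision/recall/F1 and macro F1 counted row by row."""
    per_class = {}
    for c in classes:
        tp = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = (prec, rec, f1)
    macro = sum(v[2] for v in per_class.values()) / len(classes)
    return per_class, macro


def synthetic_point_on_segment(point, seed_candidates, k, tol=1e-9):
    """True iff ``point`` lies (within tol) on the segment between some
    candidate row x and one of x's k nearest same-class neighbours.

    Exhaustive search over every (seed, neighbour) pair.
    """

    def d2(a, b):
        return sum((u - v) ** 2 for u, v in zip(a, b))

    rows = list(seed_candidates)
    for si, x in enumerate(rows):
        others = sorted(
            (j for j in range(len(rows)) if j != si),
            key=lambda j: (d2(x, rows[j]), j),
        )[:k]
        for j in others:
            nn = rows[j]
            # point = x + u*(nn-x): recover u per coordinate and check consistency
            us = []
            ok = True
            for p, a, b in zip(point, x, nn):
                if abs(b - a) > tol:
                    us.append((p - a) / (b - a))
                elif abs(p - a) > tol:
                    ok = False
                    break
            if not ok:
                continue
            if not us:  # x == nn == point
                if d2(point, x) <= tol:
                    return True
                continue
            u = us[0]
            if all(abs(v - u) < 1e-6 for v in us) and -tol <= u <= 1 + tol:
                return True
    return False
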