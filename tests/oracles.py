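"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive: from-scratch recomputation, full
enumeration, O(n^2) scans.  Nothing imports the code paths it checks beyond
shared parameter containers.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def idt_bruteforce(t, x, y, dispersion, min_duration):
    """Greedy leftmost maximal-window fixation enumeration, recomputing the
    dispersion of every candidate window from scratch.

    Returns a list of (i, j) half-open index windows.
    """
    t = np.asarray(t)
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(t)

    def disp(i, j):
        return (x[i:j].max() - x[i:j].min()) + (y[i:j].max() - y[i:j].min())

    out = []
    i = 0
    while i < n:
        # smallest window from i spanning >= min_duration (duration = t_last - t_first + 1)
        j = None
        for cand in range(i + 1, n + 1):
            if t[cand - 1] - t[i] + 1 >= min_duration:
                j = cand
                break
        if j is None:
            break
        if disp(i, j) > dispersion:
            i += 1
            continue
        while j < n and disp(i, j + 1) <= dispersion:
            j += 1
        out.append((i, j))
        i = j
    return out


def interval_union(intervals):
    """Union of half-open intervals by point-wise membership on a ms grid."""
    if not intervals:
        return []
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    member = np.zeros(hi - lo, dtype=bool)
    for a, b in intervals:
        member[a - lo : b - lo] = True
    out = []
    k = 0
    while k < len(member):
        if member[k]:
            start = k
            while k < len(member) and member[k]:
                k += 1
            out.append((start + lo, k + lo))
        else:
            k += 1
    return out


def signed_rank_exact_p(diffs):
    """Exact two-tailed signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count_le = count_ge = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le / total, count_ge / total))


def signed_rank_pmf_dp(ranks):
    """Exact null pmf of W via a dictionary DP (independent of the package's
    polynomial convolution)."""
    dist = {0.0: Fraction(1)}
    for r in ranks:
        new = {}
        for w, p in dist.items():
            half = p / 2
            new[w] = new.get(w, Fraction(0)) + half
            new[w + r] = new.get(w + r, Fraction(0)) + half
        dist = new
    return dist


def signed_rank_dp_p(diffs):
    """Exact two-tailed signed-rank p from the DP pmf (feasible for n ~ 30)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    dist = signed_rank_pmf_dp([float(r) for r in ranks])
    p_le = float(sum(p for w, p in dist.items() if w <= w_obs + 1e-9))
    p_ge = float(sum(p for w, p in dist.items() if w >= w_obs - 1e-9))
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_exact_p(a, b):
    """Exact two-tailed rank-sum p by enumerating which ranks go to sample a."""
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    r_obs = ranks[:na].sum()
    count_le = count_ge = total = 0
    for combo in itertools.combinations(ranks, na):
        s = sum(combo)
        total += 1
        if s <= r_obs + 1e-9:
            count_le += 1
        if s >= r_obs - 1e-9:
            count_ge += 1
    return min(1.0, 2.0 * min(count_le / total, count_ge / total))


def shoelace_area(coords):
    s = 0.0
    n = len(coords)
    for k in range(n):
        x0, y0 = coords[k]
        x1, y1 = coords[(k + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0
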