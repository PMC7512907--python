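"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops directly from the
definitions, deliberately ignoring vectorization, so the optimized package
code can be checked against an implementation that shares none of its
structure.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _std(x):
    return float(np.std(np.asarray(x, dtype=float)))


def sampen_bruteforce(x, m=2, r_frac=0.2):
    """Direct-count sample entropy (Chebyshev distance, self-matches excluded)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * _std(x)
    if r == 0:
        return 0.0

    def mean_match(length):
        count = n - m  # same number of templates at both lengths
        total = 0.0
        for i in range(count):
            matches = 0
            for j in range(count):
                if j == i:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    matches += 1
            total += matches / (count - 1)
        return total / count

    b_m = mean_match(m)
    b_m1 = mean_match(m + 1)
    if b_m == 0 or b_m1 == 0:
        return math.inf
    return math.log(b_m) - math.log(b_m1)


def fuzzyen_bruteforce(x, m=2, r_frac=0.2):
    """Direct-count fuzzy entropy with membership exp(-ln2*(d/r)^2)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * _std(x)
    if r == 0:
        return 0.0

    def phi(length):
        count = n - m
        total = 0.0
        for i in range(count):
            s = 0.0
            for j in range(count):
                if j == i:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                s += math.exp(-math.log(2.0) * (d / r) ** 2)
            total += s / (count - 1)
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def fuzzymen_bruteforce(x, m=2, r_frac=0.2, n_local=3, n_global=2):
    """Direct-count fuzzy measure entropy: (total, local, global)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_frac * _std(x)
    if r == 0:
        return 0.0, 0.0, 0.0
    grand = float(np.mean(x))

    def phis(length):
        count = n - m
        tot_l = tot_g = 0.0
        for i in range(count):
            wi = x[i:i + length]
            li = wi - np.mean(wi)
            gi = wi - grand
            sl = sg = 0.0
            for j in range(count):
                if j == i:
                    continue
                wj = x[j:j + length]
                lj = wj - np.mean(wj)
                gj = wj - grand
                dl = max(abs(li[k] - lj[k]) for k in range(length))
                dg = max(abs(gi[k] - gj[k]) for k in range(length))
                sl += math.exp(-(dl**n_local) / r)
                sg += math.exp(-(dg**n_global) / r)
            tot_l += sl / (count - 1)
            tot_g += sg / (count - 1)
        return tot_l / count, tot_g / count

    phi_l_m, phi_g_m = phis(m)
    phi_l_m1, phi_g_m1 = phis(m + 1)
    local = -math.log(phi_l_m1 / phi_l_m)
    glob = -math.log(phi_g_m1 / phi_g_m)
    return local + glob, local, glob


def mwu_exact_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Feasible only for tiny samples.  Returns (U_a, p).  The two-sided p is
    the probability, over all C(n_a+n_b, n_a) equally likely assignments of
    the pooled values to the two groups, that |U - mean| is at least as
    extreme as observed.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a, n_b = len(a), len(b)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    observed = u_stat(a, b)
    mean_u = n_a * n_b / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n_a + n_b) if i not in idx]
        u = u_stat(ga, gb)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return observed, count / total


def mix_sequence_reference(n, p, rng, period=12):
    """Reference MIX(p) draw: must mirror the package generator's definition."""
    i = np.arange(n)
    s = math.sqrt(2.0) * np.sin(2.0 * math.pi * i / period)
    z = rng.random(n) < p
    e = rng.uniform(-math.sqrt(3.0), math.sqrt(3.0), size=n)
    return np.where(z, e, s)
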