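"""Independent brute-force reference implementations used only by the tests.

These deliberately re-derive each quantity from its definition (explicit
loops, scipy distribution objects) rather than reusing the package's
vectorized code paths.
"""

import numpy as np
from scipy.stats import binom, nbinom, poisson


def average_ranks(x):
    """1-based ranks with ties averaged (explicit loop implementation)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    s = x[order]
    out = np.empty(len(x))
    start = 0
    for k in range(1, len(x) + 1):
        if k == len(x) or s[k] != s[start]:
            out[order[start:k]] = (start + 1 + k) / 2.0
            start = k
    return out


def tmm_factors_bruteforce(counts, trim_m=0.30, trim_a=0.05):
    """Weighted doubly trimmed mean of M-values, evaluated from the formula."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = []
    for j in range(x.shape[1]):
        if j == ref:
            raw.append(1.0)
            continue
        o, r = x[:, j], x[:, ref]
        both = (o > 0) & (r > 0)
        o, r = o[both], r[both]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        v = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            raw.append(1.0)
            continue
        n = len(m)
        lo_l = np.floor(n * trim_m) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * trim_a) + 1
        hi_s = n + 1 - lo_s
        rm, ra = average_ranks(m), average_ranks(a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        raw.append(2.0 ** (np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])))
    raw = np.array(raw)
    return raw / np.exp(np.mean(np.log(raw)))


def exact_pvalue_bruteforce(counts_a, counts_b, phi, mu=10.0):
    """Minimum-likelihood two-sided conditional p-value by full enumeration.

    Assumes equal library sizes. The group sums are NB (or Poisson) with a
    shared success probability, so every split of the total is enumerated
    with scipy pmfs and normalized.
    """
    n_a, n_b = len(counts_a), len(counts_b)
    s_a, s_b = int(sum(counts_a)), int(sum(counts_b))
    t = s_a + s_b
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if phi > 0:
        r = 1.0 / phi
        p = r / (r + mu)
        pr = nbinom.pmf(s, n_a * r, p) * nbinom.pmf(t - s, n_b * r, p)
    else:
        pr = poisson.pmf(s, n_a * mu) * poisson.pmf(t - s, n_b * mu)
    pr = pr / pr.sum()
    return float(pr[pr <= pr[s_a] * (1.0 + 1e-12)].sum())


def binomial_two_sided(counts_a, counts_b):
    """Poisson-limit check: conditional law is Binomial(t, n_a/(n_a+n_b))."""
    n_a, n_b = len(counts_a), len(counts_b)
    s_a = int(sum(counts_a))
    t = s_a + int(sum(counts_b))
    pm = binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    return float(pm[pm <= pm[s_a] * (1.0 + 1e-12)].sum())


def hypergeom_closed_form():
    """P[X >= 4] for N=10, K=5, n=4: C(5,4) C(5,0) / C(10,4) = 5/210."""
    from math import comb

    return comb(5, 4) * comb(5, 0) / comb(10, 4)
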