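"""Independent, loop-based reference implementations used only by the tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops, direct formula transcription, factorial arithmetic.  They are the
yardstick the production implementations are compared against.
"""

from __future__ import annotations

import math

import numpy as np

MAD = 1.4826


def _median(vals):
    return float(np.median(np.asarray(vals, dtype=float)))


def _mad(vals, center=None):
    vals = np.asarray(vals, dtype=float)
    c = _median(vals) if center is None else center
    return MAD * _median([abs(v - c) for v in vals])


def t_pooled(normal, tumor):
    n1, n2 = len(normal), len(tumor)
    m1 = sum(normal) / n1
    m2 = sum(tumor) / n2
    v1 = sum((x - m1) ** 2 for x in normal) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in tumor) / (n2 - 1)
    s2p = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if s2p <= 0:
        return float("nan")
    return (m2 - m1) / math.sqrt(s2p * (1 / n1 + 1 / n2))


def copa(normal, tumor, r=90.0):
    allv = list(normal) + list(tumor)
    med = _median(allv)
    mad = _mad(allv, med)
    if mad <= 0:
        return float("nan")
    z_tumor = [(x - med) / mad for x in tumor]
    return float(np.percentile(z_tumor, r))


def outlier_sum(normal, tumor):
    allv = list(normal) + list(tumor)
    med = _median(allv)
    mad = _mad(allv, med)
    if mad <= 0:
        return float("nan")
    z_all = [(x - med) / mad for x in allv]
    q75, q25 = np.percentile(z_all, [75, 25])
    cutoff = q75 + (q75 - q25)
    total = 0.0
    for x in tumor:
        z = (x - med) / mad
        if z > cutoff:
            total += z
    return total


def ort(normal, tumor):
    med_n = _median(normal)
    med_t = _median(tumor)
    q75, q25 = np.percentile(list(normal), [75, 25])
    cutoff = q75 + (q75 - q25)
    residuals = [abs(x - med_n) for x in normal] + [abs(x - med_t) for x in tumor]
    scale = MAD * _median(residuals)
    if scale <= 0:
        return float("nan")
    total = 0.0
    for x in tumor:
        if x > cutoff:
            total += (x - med_n) / scale
    return total


def most(normal, tumor, mu, sigma):
    """MOST via an explicit loop over ordered subset sizes k."""
    med_n = _median(normal)
    mad_n = _mad(normal, med_n)
    if mad_n <= 0:
        return float("nan")
    z = sorted(((x - med_n) / mad_n for x in tumor), reverse=True)
    best = -float("inf")
    running = 0.0
    for k in range(1, len(z) + 1):
        running += z[k - 1]
        best = max(best, (running - mu[k - 1]) / sigma[k - 1])
    return best


def two_sided(stat_fn, normal, tumor, **kw):
    """Larger of the statistic on the original and the negated values."""
    up = stat_fn(list(normal), list(tumor), **kw)
    dn = stat_fn([-x for x in normal], [-x for x in tumor], **kw)
    if math.isnan(up) and math.isnan(dn):
        return float("nan")
    return max(up, dn)


def hypergeom_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by factorial arithmetic."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    from fractions import Fraction

    return float(Fraction(total, denom))


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, direct transcription."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def alpha_beta(edges, dereg):
    """(alpha, beta) per miRNA by exhaustive per-gene degree enumeration.

    ``edges`` is an iterable of (mirna, gene) pairs over the FULL network;
    the subnetwork is the restriction to ``dereg`` genes.
    """
    sub = [(m, g) for m, g in edges if g in dereg]
    genes = {}
    for m, g in sub:
        genes.setdefault(g, set()).add(m)
    out = {}
    for m, g in sub:
        a, b = out.get(m, (0, 0))
        b += 1
        if len(genes[g]) == 1:
            a += 1
        out[m] = (a, b)
    return out
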