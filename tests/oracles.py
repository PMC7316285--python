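"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain loops over definitions —
no interval index, no vectorization, no shared code with the package —
so that agreement with the package is informative.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values straight from the definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def strip_chr(name):
    s = str(name)
    return s[3:].upper() if s.lower().startswith("chr") else s.upper()


def qtl_pass_genes(genes, qtls):
    """All-pairs any-overlap scan; genes/qtls are lists of dicts."""
    passed = set()
    for g in genes:
        for q in qtls:
            if strip_chr(g["chromosome"]) != strip_chr(q["chromosome"]):
                continue
            if g["start"] <= q["span_end"] and q["span_start"] <= g["end"]:
                passed.add(g["gene_id"])
    return passed


def snp_pass_genes(genes, snps, max_mb=5.0):
    """All-pairs nearest-edge distance scan with a strict threshold."""
    passed = set()
    for g in genes:
        for s in snps:
            if strip_chr(g["chromosome"]) != strip_chr(s["chromosome"]):
                continue
            if g["start"] <= s["position"] <= g["end"]:
                d = 0.0
            else:
                d = min(abs(s["position"] - g["start"]), abs(s["position"] - g["end"])) / 1e6
            if d < max_mb:
                passed.add(g["gene_id"])
                break
    return passed


def ks_statistic_vs_fitted_normal(values):
    """sup |ECDF - Phi((x - mean)/sd)| computed point by point."""
    from scipy.stats import norm

    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    mu, sd = x.mean(), x.std(ddof=1)
    cdf = norm.cdf((x - mu) / sd)
    d = 0.0
    for i in range(n):
        d = max(d, (i + 1) / n - cdf[i], cdf[i] - i / n)
    return d


def permutation_pvalue(a, b, n_perm=20000, seed=0):
    """Two-sided permutation p-value for the difference in means."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
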