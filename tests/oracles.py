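"""Independent brute-force reference implementations used only by tests.

Each oracle restates the operation's definition as directly as possible —
double loops, full enumeration — with no shared code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb


def bh_stepup(p):
    """Benjamini-Hochberg step-up from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def overlap_counts(reads, peaks):
    """O(n*m) double loop: read [s,e) overlaps peak [ps,pe) iff ps < e and pe > s."""
    per_peak = {}
    assigned = 0
    for p in peaks:
        per_peak[p.peak_id] = sum(
            1
            for r in reads
            if r.chrom == p.chrom and p.start < r.end and p.end > r.start
        )
    for r in reads:
        if any(
            r.chrom == p.chrom and p.start < r.end and p.end > r.start for p in peaks
        ):
            assigned += 1
    return per_peak, assigned, len(reads)


def chi2_textbook(table):
    """Uncorrected Pearson chi-squared applied cell by cell."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    resid = np.zeros_like(table)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
            resid[i, j] = (table[i, j] - e) / np.sqrt(e)
    return stat, resid


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    table = np.asarray(table, dtype=int)
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {x: prob(x) for x in range(lo, hi + 1)}
    total = sum(probs.values())
    obs = probs[a]
    # tolerate float fuzz exactly as R/scipy do (relative 1e-7)
    cutoff = obs * (1 + 1e-7)
    return sum(v for v in probs.values() if v <= cutoff) / total


def nearest_gene_scan(peaks, genes):
    """Brute-force nearest gene per peak with the lexicographic tie rule."""
    out = {}
    for p in peaks:
        center = (p.start + p.end) // 2
        best = None
        for g in genes:
            if g.chrom != p.chrom:
                continue
            d = abs(center - g.tls)
            if best is None or d < best[1] or (d == best[1] and g.gene_id < best[0]):
                best = (g.gene_id, d)
        out[p.peak_id] = best
    return out


def window_scan(gene, peaks, window):
    """Brute-force inclusive window query around a TLS."""
    return sorted(
        p.peak_id
        for p in peaks
        if p.chrom == gene.chrom and abs((p.start + p.end) // 2 - gene.tls) <= window
    )
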