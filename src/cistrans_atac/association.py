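"""Peak-gene association statistics and landscape contrasts.

Links peaks to genes by center-to-TLS distance, then asks, per stage,
whether differential accessibility (DA) near a gene predicts its
differential expression (DE): a peaks-focused 2x2 test (is the nearest
gene of a DA peak DE?), a gene-focused test (does a DE gene have any DA
peak within a window?), and a regulatory-mode-focused pair restricted to
DE genes (is cis-based DE enriched for nearby DA?).  Landscape contrasts
compare proximal vs distal peaks and gene classes (all genes,
transcription factors, GRN genes) in DA rate, regulatory mode, effect
size, and nearby-peak density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

from .datatypes import (
    DISTAL_BP,
    PROXIMAL_BP,
    GeneModel,
    PeakInterval,
    link_category,
)

__all__ = [
    "AssociationResult",
    "nearest_gene",
    "peaks_in_window",
    "gene_window_counts",
    "chi2_independence",
    "peaks_focused_test",
    "gene_focused_test",
    "regmode_focused_test",
    "category_enrichment",
    "group_compare",
    "peak_density",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """A contingency test with its Pearson residuals.

    Residuals are (observed - expected) / sqrt(expected), reported without
    any continuity adjustment; the test statistic may be continuity
    corrected when the table is 2x2.
    """

    name: str
    table: np.ndarray
    statistic: float
    df: int
    p: float
    residuals: np.ndarray
    odds_ratio: float | None = None
    method: str = "chi2"


# ---------------------------------------------------------------------------
# Geometry: nearest gene and windowed queries
# ---------------------------------------------------------------------------


def nearest_gene(
    peaks: Sequence[PeakInterval], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Nearest gene per peak by |peak center - TLS| on the same chromosome.

    Distances are strand-agnostic.  Exact distance ties break to the
    lexicographically smaller gene_id.  Peaks on a chromosome without genes
    get a null link (gene_id NA) and are logged.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: (g.tls, g.gene_id))
        arrays[chrom] = (
            np.array([g.tls for g in gs]),
            [g.gene_id for g in gs],
        )
    rows = []
    n_absent = 0
    for p in peaks:
        if p.chrom not in arrays:
            n_absent += 1
            rows.append((p.peak_id, pd.NA, np.nan, pd.NA))
            continue
        tls, ids = arrays[p.chrom]
        c = p.center
        i = int(np.searchsorted(tls, c))
        best_gene, best_dist = None, None
        for j in (i - 1, i):
            if 0 <= j < len(tls):
                d = abs(c - int(tls[j]))
                if (
                    best_dist is None
                    or d < best_dist
                    or (d == best_dist and ids[j] < best_gene)
                ):
                    best_gene, best_dist = ids[j], d
        # equidistant genes sharing a TLS coordinate: scan neighbors with equal distance
        for j in range(i - 2, -1, -1):
            if abs(c - int(tls[j])) != best_dist:
                break
            if ids[j] < best_gene:
                best_gene = ids[j]
        for j in range(i + 1, len(tls)):
            if abs(c - int(tls[j])) != best_dist:
                break
            if ids[j] < best_gene:
                best_gene = ids[j]
        rows.append((p.peak_id, best_gene, float(best_dist), link_category(best_dist)))
    if n_absent:
        logger.warning("%d peak(s) lie on chromosomes with no genes", n_absent)
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance", "category"]
    ).set_index("peak_id", drop=False)


def peaks_in_window(
    gene: GeneModel, peaks: Sequence[PeakInterval], window: int = DISTAL_BP
) -> list[str]:
    """Peak ids whose center lies within +/- window bp of the TLS, inclusive."""
    if window <= 0:
        raise ValueError("window must be positive")
    return [
        p.peak_id
        for p in peaks
        if p.chrom == gene.chrom and abs(p.center - gene.tls) <= window
    ]


def gene_window_counts(
    genes: Sequence[GeneModel],
    peaks: Sequence[PeakInterval],
    window: int = DISTAL_BP,
    indicator: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-gene counts of nearby peaks (and of flagged peaks, if given).

    Genes with no peak within the window contribute zero counts, not NA.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = [p for p in peaks if p.chrom == chrom]
        centers = np.array([p.center for p in ps])
        order = np.argsort(centers, kind="stable")
        flags = np.array(
            [bool(indicator.get(ps[i].peak_id, False)) if indicator else False for i in order]
        )
        by_chrom[chrom] = (centers[order], flags)
    rows = []
    for g in genes:
        if g.chrom not in by_chrom:
            rows.append((g.gene_id, 0, 0))
            continue
        centers, flags = by_chrom[g.chrom]
        lo = int(np.searchsorted(centers, g.tls - window, side="left"))
        hi = int(np.searchsorted(centers, g.tls + window, side="right"))
        rows.append((g.gene_id, hi - lo, int(flags[lo:hi].sum())))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_peaks", "n_flagged"]
    ).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------


def chi2_independence(
    table: np.ndarray | Sequence[Sequence[int]],
    continuity: bool = True,
    name: str = "chi2",
) -> AssociationResult:
    """Pearson chi-squared test of independence with Pearson residuals.

    The Yates continuity correction (gamma = 0.5) applies only when
    requested and the table is 2x2; residuals are always uncorrected.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "contingency table has a zero margin; merge the empty category"
        )
    r, c = table.shape
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    gamma = 0.5 if (continuity and table.shape == (2, 2)) else 0.0
    adj = np.maximum(np.abs(table - expected) - gamma, 0.0)
    statistic = float((adj**2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    residuals = (table - expected) / np.sqrt(expected)
    odds = None
    if table.shape == (2, 2) and table[0, 1] * table[1, 0] > 0:
        odds = float(table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0]))
    return AssociationResult(
        name=name,
        table=table,
        statistic=statistic,
        df=df,
        p=p,
        residuals=residuals,
        odds_ratio=odds,
        method="chi2_yates" if gamma else "chi2",
    )


def _two_by_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rows: a True/False; columns: b True/False."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    return np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )


def peaks_focused_test(
    links: pd.DataFrame,
    da_by_peak: Mapping[str, bool] | pd.Series,
    de_by_gene: Mapping[str, bool] | pd.Series,
    name: str = "peaks_focused",
    continuity: bool = True,
) -> AssociationResult:
    """2x2 test: (peak DA?) x (its nearest gene DE?).

    Rows index DA status, columns DE status, with the DA-and-DE cell at
    (0, 0).  Peaks without a nearest-gene link are excluded and logged.
    """
    linked = links.dropna(subset=["gene_id"])
    dropped = len(links) - len(linked)
    if dropped:
        logger.warning("peaks_focused: excluded %d unlinked peak(s)", dropped)
    da = np.array([bool(da_by_peak[p]) for p in linked["peak_id"]])
    de = np.array([bool(de_by_gene[g]) for g in linked["gene_id"]])
    return chi2_independence(_two_by_two(da, de), continuity=continuity, name=name)


def gene_focused_test(
    genes: Sequence[GeneModel],
    peaks: Sequence[PeakInterval],
    da_by_peak: Mapping[str, bool] | pd.Series,
    de_by_gene: Mapping[str, bool] | pd.Series,
    window: int = DISTAL_BP,
    name: str = "gene_focused",
    continuity: bool = True,
) -> AssociationResult:
    """2x2 test: (gene DE?) x (>= 1 DA peak within the window?)."""
    counts = gene_window_counts(genes, peaks, window, indicator=dict(da_by_peak))
    de = np.array([bool(de_by_gene[g.gene_id]) for g in genes])
    has_da = counts.loc[[g.gene_id for g in genes], "n_flagged"].to_numpy() > 0
    return chi2_independence(_two_by_two(de, has_da), continuity=continuity, name=name)


def regmode_focused_test(
    genes: Sequence[GeneModel],
    peaks: Sequence[PeakInterval],
    da_by_peak: Mapping[str, bool] | pd.Series,
    expr_mode_by_gene: Mapping[str, str] | pd.Series,
    de_by_gene: Mapping[str, bool] | pd.Series,
    window: int = DISTAL_BP,
    continuity: bool = True,
) -> tuple[AssociationResult, AssociationResult]:
    """Among DE genes: (expression mode cis?) x (nearby DA peak?), and the
    mirrored test for trans."""
    de_genes = [g for g in genes if bool(de_by_gene[g.gene_id])]
    if not de_genes:
        raise ValueError("no differentially expressed genes to test")
    counts = gene_window_counts(de_genes, peaks, window, indicator=dict(da_by_peak))
    has_da = counts.loc[[g.gene_id for g in de_genes], "n_flagged"].to_numpy() > 0
    modes = np.array([str(expr_mode_by_gene[g.gene_id]) for g in de_genes])
    res_cis = chi2_independence(
        _two_by_two(modes == "cis", has_da), continuity=continuity, name="regmode_cis"
    )
    res_trans = chi2_independence(
        _two_by_two(modes == "trans", has_da), continuity=continuity, name="regmode_trans"
    )
    return res_cis, res_trans


def category_enrichment(
    in_category: np.ndarray, indicator: np.ndarray, name: str = "enrichment"
) -> AssociationResult:
    """Fisher's exact test of a binary category against a binary indicator.

    Reports the conditional maximum-likelihood odds ratio and the exact
    two-sided p (the sum of hypergeometric probabilities no larger than the
    observed table's).
    """
    table = _two_by_two(np.asarray(in_category), np.asarray(indicator))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = float(_cond_odds_ratio(table, kind="conditional").statistic)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    residuals = (table - expected) / np.sqrt(expected)
    return AssociationResult(
        name=name,
        table=table.astype(float),
        statistic=orr,
        df=1,
        p=p,
        residuals=residuals,
        odds_ratio=orr,
        method="fisher_2x2",
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def group_compare(
    groups: Mapping[str, Sequence[float]], method: str = "welch_t", alpha: float = 0.05
) -> dict:
    """Compare value distributions across groups.

    ``welch_t`` (2 groups, unequal-variance t with Welch-Satterthwaite df),
    ``ks`` (2 groups, max ECDF difference with asymptotic p), or
    ``anova_scheffe`` (one-way F plus pairwise Scheffe decisions at level
    alpha, robust to very unequal group sizes).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")

    if method == "welch_t":
        if len(arrays) != 2:
            raise ValueError("welch_t compares exactly 2 groups")
        a, b = arrays
        if a.var(ddof=1) < 1e-12 and b.var(ddof=1) < 1e-12:
            if abs(a.mean() - b.mean()) < 1e-12:
                return {"method": method, "statistic": 0.0, "p": 1.0}
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {"method": method, "statistic": float(t), "p": float(p)}

    if method == "ks":
        if len(arrays) != 2:
            raise ValueError("ks compares exactly 2 groups")
        d, p = stats.ks_2samp(arrays[0], arrays[1], method="asymp")
        return {"method": method, "statistic": float(d), "p": float(p)}

    if method == "anova_scheffe":
        f, p = stats.f_oneway(*arrays)
        sizes = np.array([len(a) for a in arrays])
        means = np.array([a.mean() for a in arrays])
        n_total = sizes.sum()
        k = len(arrays)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        df_w = n_total - k
        msw = ssw / df_w if df_w > 0 else np.nan
        pairwise = {}
        crit = (k - 1) * stats.f.ppf(1 - alpha, k - 1, df_w)
        for i in range(k):
            for j in range(i + 1, k):
                denom = msw * (1 / sizes[i] + 1 / sizes[j])
                t2 = (means[i] - means[j]) ** 2 / denom if denom > 1e-12 else 0.0
                p_pair = float(stats.f.sf(t2 / (k - 1), k - 1, df_w))
                pairwise[(labels[i], labels[j])] = {
                    "statistic": float(t2),
                    "significant": bool(t2 > crit),
                    "p": p_pair,
                }
        return {
            "method": method,
            "statistic": float(f),
            "p": float(p),
            "pairwise": pairwise,
        }

    raise ValueError(f"unknown method {method!r}")


def peak_density(
    genes: Sequence[GeneModel],
    peaks: Sequence[PeakInterval],
    window: int = DISTAL_BP,
) -> pd.Series:
    """Per-gene count of peaks with center within +/- window of the TLS."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene subset must be nonempty")
    counts = gene_window_counts(genes, peaks, window)
    return counts["n_peaks"]
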