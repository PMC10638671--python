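"""Count-matrix construction, filtering, normalization, PCA and FRIP.

The preprocessing conventions follow common bulk ATAC-seq practice: a
counts-per-million (CPM) low-count filter voted over the non-split samples,
median-of-ratios size factors against a per-peak geometric-mean reference,
a log2(normalized + pseudocount) stabilizing transform, and sample-space
PCA on the transformed matrix.
"""

from __future__ import annotations

import math
import warnings
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ALLELE_TOTAL,
    CROSS_HYBRID,
    CountMatrix,
    PeakInterval,
    SampleDescriptor,
    make_sample_id,
)

__all__ = [
    "count_reads_in_intervals",
    "frip",
    "cpm_filter",
    "size_factors",
    "transform",
    "pca",
]


# ---------------------------------------------------------------------------
# Interval counting and FRIP
# ---------------------------------------------------------------------------


def _by_chrom(intervals: Sequence[PeakInterval]) -> dict[str, list[PeakInterval]]:
    out: dict[str, list[PeakInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def count_reads_in_intervals(
    reads: Sequence[PeakInterval], peaks: Sequence[PeakInterval]
) -> tuple[pd.Series, int, int]:
    """Count reads overlapping each peak by >= 1 bp (half-open intervals).

    A read overlapping k > 1 peaks is counted once per peak but only once
    in the assigned tally.  Returns (per-peak counts, assigned, total).
    """
    reads_by_chrom = _by_chrom(reads)
    counts = pd.Series(0, index=[p.peak_id for p in peaks], dtype=np.int64)

    # per-peak counts: n_reads - (#reads ending before peak) - (#reads starting after)
    starts_sorted: dict[str, np.ndarray] = {}
    ends_sorted: dict[str, np.ndarray] = {}
    for chrom, rs in reads_by_chrom.items():
        starts_sorted[chrom] = np.sort(np.array([r.start for r in rs]))
        ends_sorted[chrom] = np.sort(np.array([r.end for r in rs]))
    for p in peaks:
        if p.chrom not in starts_sorted:
            continue
        starts = starts_sorted[p.chrom]
        ends = ends_sorted[p.chrom]
        n = len(starts)
        before = np.searchsorted(ends, p.start, side="right")  # end <= start
        after = n - np.searchsorted(starts, p.end, side="left")  # start >= end
        counts[p.peak_id] = n - before - after

    # assigned tally against the merged union of peaks
    assigned = 0
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ps in _by_chrom(peaks).items():
        ivs = sorted((p.start, p.end) for p in ps)
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    for chrom, rs in reads_by_chrom.items():
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        s = np.array([r.start for r in rs])
        e = np.array([r.end for r in rs])
        idx = np.searchsorted(ms, s, side="right") - 1
        hit_left = (idx >= 0) & (me[np.clip(idx, 0, None)] > s)
        nxt = idx + 1
        hit_right = (nxt < len(ms)) & (ms[np.clip(nxt, None, len(ms) - 1)] < e)
        assigned += int((hit_left | hit_right).sum())
    return counts, assigned, len(reads)


def frip(reads: Sequence[PeakInterval], peaks: Sequence[PeakInterval]) -> float:
    """Fraction of reads overlapping (>= 1 bp) the peak set."""
    if len(reads) == 0:
        raise ValueError("FRIP is undefined for zero reads")
    _, assigned, total = count_reads_in_intervals(reads, peaks)
    return assigned / total


def frip_per_set(
    read_sets: Mapping[str, Sequence[PeakInterval]], peaks: Sequence[PeakInterval]
) -> dict[str, float]:
    """FRIP per named read set, e.g. one per hybrid allele-of-origin bin."""
    return {name: frip(rs, peaks) for name, rs in read_sets.items()}


# ---------------------------------------------------------------------------
# CPM filter
# ---------------------------------------------------------------------------


def _default_exclude(d: SampleDescriptor) -> bool:
    return d.allele != ALLELE_TOTAL


def cpm_filter(
    cm: CountMatrix,
    descriptors: Sequence[SampleDescriptor] | None = None,
    min_cpm: float = 3.0,
    min_fraction: float = 1 / 3,
    exclude: Callable[[SampleDescriptor], bool] | None = None,
) -> CountMatrix:
    """Drop peaks below ``min_cpm`` CPM in fewer than ceil(min_fraction * n)
    of the included samples.

    By default the split hybrid allele columns are excluded from the vote
    (they are half-depth views of the hybrid library) but are retained in
    the output matrix.  Pass ``exclude=lambda d: False`` to let every
    column vote.
    """
    if exclude is None:
        exclude = _default_exclude
    if descriptors is None:
        included = list(cm.sample_ids)
    else:
        by_id = {d.sample_id: d for d in descriptors}
        included = [s for s in cm.sample_ids if not exclude(by_id[s])]
    if not included:
        raise ValueError("no samples left to vote in the CPM filter")
    sub = cm.counts[included]
    libsize = sub.sum(axis=0)
    if (libsize <= 0).any():
        empty = libsize.index[libsize <= 0][0]
        raise ValueError(f"library size is zero for included sample {empty!r}")
    cpm = sub * 1e6 / libsize
    need = math.ceil(min_fraction * len(included) - 1e-9)
    votes = (cpm >= min_cpm).sum(axis=1)
    keep = votes >= need
    if not keep.any():
        warnings.warn("CPM filter removed every peak", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], None)


# ---------------------------------------------------------------------------
# Size factors (median-of-ratios)
# ---------------------------------------------------------------------------


def size_factors(
    cm: CountMatrix,
    descriptors: Sequence[SampleDescriptor] | None = None,
    policy: str = "inherit",
) -> CountMatrix:
    """Median-of-ratios size factors against the per-peak geometric mean.

    Factors are estimated from the non-split columns only.  Under the
    default ``"inherit"`` policy each hybrid allele column receives its
    parent hybrid total column's factor, so allelic ratios within a library
    are never renormalized away.  ``policy="independent"`` estimates a
    factor for every column instead.
    """
    if policy not in ("inherit", "independent"):
        raise ValueError(f"unknown size-factor policy {policy!r}")
    if policy == "inherit" and descriptors is None:
        raise ValueError("the 'inherit' policy requires sample descriptors")

    if policy == "independent" or descriptors is None:
        estimate_cols = list(cm.sample_ids)
    else:
        by_id = {d.sample_id: d for d in descriptors}
        estimate_cols = [
            s for s in cm.sample_ids if by_id[s].allele == ALLELE_TOTAL
        ]

    sub = cm.counts[estimate_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(sub)
    all_positive = np.isfinite(logs).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no peak has nonzero counts in every included sample; "
            "apply the CPM filter first"
        )
    ref = logs[all_positive].mean(axis=1)  # per-peak log geometric mean
    log_factors = np.median(logs[all_positive] - ref[:, None], axis=0)
    factors = pd.Series(np.exp(log_factors), index=estimate_cols)

    full = pd.Series(index=cm.sample_ids, dtype=float)
    full.loc[estimate_cols] = factors
    if policy == "inherit" and descriptors is not None:
        by_id = {d.sample_id: d for d in descriptors}
        for sid in cm.sample_ids:
            d = by_id[sid]
            if d.allele != ALLELE_TOTAL:
                parent = make_sample_id(CROSS_HYBRID, d.stage, d.replicate)
                if parent not in factors.index:
                    raise ValueError(
                        f"allele column {sid!r} has no hybrid total column "
                        f"{parent!r} to inherit a size factor from"
                    )
                full.loc[sid] = factors[parent]
    if full.isna().any():
        missing = full.index[full.isna()][0]
        raise ValueError(f"no size factor assigned for sample {missing!r}")
    return CountMatrix(cm.counts, full)


# ---------------------------------------------------------------------------
# Transform and PCA
# ---------------------------------------------------------------------------


def transform(cm: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), monotone within a column."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    return np.log2(cm.normalized() + pseudocount)


def pca(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA of a transformed peaks-by-samples matrix.

    Samples are the observations; each peak (feature) is centered across
    samples, with no scaling.  Returns (coordinates indexed by sample,
    fraction of variance per retained component).  A constant matrix has
    zero components.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x peaks
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-12:
        coords = pd.DataFrame(index=matrix.columns)
        return coords, np.array([])
    keep = var > 1e-12 * var[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| element of each component positive
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    coords = pd.DataFrame(
        u * s,
        index=matrix.columns,
        columns=[f"PC{k + 1}" for k in range(len(s))],
    )
    fractions = s**2 / (s**2).sum()
    return coords, fractions
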