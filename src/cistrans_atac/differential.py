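"""Negative-binomial differential accessibility tests.

The engine is a plug-in Wald contrast on size-factor-normalized group
means, with a per-peak method-of-moments dispersion pooled across replicate
groups, plus a ratio-divergence test that compares the parental log2 ratio
(L_P) with the hybrid allelic log2 ratio (L_H).  A trans influence moves
L_P away from L_H (in the hybrid's common nuclear environment both alleles
see the same trans factors), so the difference L_P - L_H isolates the
trans component of divergence.

Multiplicity control is Benjamini-Hochberg within a family, one family per
(contrast, stage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ALLELE_MATERNAL,
    ALLELE_PATERNAL,
    ALLELE_TOTAL,
    CROSS_HYBRID,
    CROSS_MATERNAL,
    CROSS_PATERNAL,
    CountMatrix,
    SampleDescriptor,
)

__all__ = [
    "estimate_dispersion",
    "moderate_dispersion",
    "wald_test",
    "ratio_divergence_test",
    "bh_adjust",
    "stage_contrasts",
    "CONTRAST_PARENTS",
    "CONTRAST_HYBRID_ALLELES",
    "CONTRAST_VS_MATERNAL",
    "CONTRAST_VS_PATERNAL",
    "CONTRAST_RATIO_DIVERGENCE",
]

LN2 = np.log(2.0)

CONTRAST_PARENTS = "parents"
CONTRAST_HYBRID_ALLELES = "hybrid_alleles"
CONTRAST_VS_MATERNAL = "hybrid_vs_maternal"
CONTRAST_VS_PATERNAL = "hybrid_vs_paternal"
CONTRAST_RATIO_DIVERGENCE = "ratio_divergence"


def estimate_dispersion(
    cm: CountMatrix,
    groups: Mapping[str, Sequence[str]],
    floor: float = 1e-8,
) -> pd.Series:
    """Per-peak method-of-moments NB dispersion pooled across groups.

    With per-group normalized mean m and sample variance s^2 (ddof=1) and
    weight w = n - 1::

        alpha_hat = max(floor, sum_g (s2_g - m_g) * w_g / sum_g m_g^2 * w_g)

    Groups with a single replicate carry no information and are skipped;
    if every group is a singleton an error demands replicates.
    """
    norm = cm.normalized()
    num = np.zeros(len(cm.peak_ids))
    den = np.zeros(len(cm.peak_ids))
    informative = False
    for label, sample_ids in groups.items():
        sub = norm[list(sample_ids)].to_numpy()
        n = sub.shape[1]
        if n < 2:
            continue
        informative = True
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = n - 1
        num += (s2 - m) * w
        den += m**2 * w
    if not informative:
        raise ValueError(
            "dispersion is not estimable: every group has a single replicate"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.where(den > 0, den, 1.0), floor)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=cm.peak_ids, name="dispersion")


def moderate_dispersion(dispersion: pd.Series, weight: float = 0.5) -> pd.Series:
    """Shrink per-peak dispersions toward the across-peak median.

    The raw per-peak method-of-moments estimate has few degrees of freedom
    (replicate groups are small), and plugging a noisy dispersion into the
    Wald variance inflates the test's tails.  Borrowing strength across
    peaks — here a convex combination with the across-peak median —
    restores near-nominal type-I error while preserving genuine
    peak-to-peak differences.  ``weight`` is the share kept by the per-peak
    estimate.
    """
    if not 0 <= weight <= 1:
        raise ValueError("weight must lie in [0, 1]")
    prior = float(np.median(dispersion))
    return weight * dispersion + (1 - weight) * prior


def _group_mean(cm: CountMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    if len(sample_ids) == 0:
        raise ValueError("contrast group is empty")
    return cm.normalized()[list(sample_ids)].to_numpy().mean(axis=1)


def wald_test(
    cm: CountMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    dispersion: pd.Series,
    contrast: str,
    pseudocount: float = 0.5,
    stage: str | None = None,
) -> pd.DataFrame:
    """NB Wald contrast of two sample groups on the normalized scale.

    log2_ratio = log2((m1 + psi) / (m2 + psi)); the per-group variance of
    the log mean is the delta-method NB form (m + alpha m^2) / (n (m+psi)^2)
    evaluated at the group mean, psi keeping it finite at zero counts.
    z is log2_ratio over its log2-scale standard error, with a two-sided
    normal p-value.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    m1 = _group_mean(cm, group1)
    m2 = _group_mean(cm, group2)
    alpha = dispersion.reindex(cm.peak_ids).to_numpy()
    n1, n2 = len(group1), len(group2)

    log2_ratio = np.log2((m1 + pseudocount) / (m2 + pseudocount))
    var_ln1 = (m1 + alpha * m1**2) / (n1 * (m1 + pseudocount) ** 2)
    var_ln2 = (m2 + alpha * m2**2) / (n2 * (m2 + pseudocount) ** 2)
    se = np.sqrt(var_ln1 + var_ln2) / LN2  # log2 units
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2_ratio / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # both group means zero: ratio 0 by convention, no evidence
    degenerate = (m1 == 0) & (m2 == 0)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame(
        {
            "peak_id": cm.peak_ids,
            "contrast": contrast,
            "log2_ratio": log2_ratio,
            "se": se,
            "z": z,
            "p": p,
        }
    ).set_index("peak_id", drop=False)
    if stage is not None:
        out.insert(1, "stage", stage)
    return out


def ratio_divergence_test(res_p: pd.DataFrame, res_h: pd.DataFrame) -> pd.DataFrame:
    """Trans test: does the parental ratio differ from the hybrid allelic ratio?

    z = (L_P - L_H) / sqrt(se_P^2 + se_H^2); the log2_ratio column stores
    L_P - L_H, the trans component of the divergence.
    """
    if not res_p.index.equals(res_h.index):
        raise ValueError("parental and hybrid-allele results cover different peaks")
    diff = res_p["log2_ratio"].to_numpy() - res_h["log2_ratio"].to_numpy()
    se = np.sqrt(res_p["se"].to_numpy() ** 2 + res_h["se"].to_numpy() ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    out = pd.DataFrame(
        {
            "peak_id": res_p["peak_id"],
            "contrast": CONTRAST_RATIO_DIVERGENCE,
            "log2_ratio": diff,
            "se": se,
            "z": z,
            "p": p,
        },
        index=res_p.index,
    )
    if "stage" in res_p.columns:
        out.insert(1, "stage", res_p["stage"])
    return out


def bh_adjust(p: pd.Series | np.ndarray, family: pd.Series | None = None) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment, independently per family."""
    p = pd.Series(p).astype(float)
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)].iloc[0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    if family is None:
        adj = multipletests(p.to_numpy(), method="fdr_bh")[1]
        return pd.Series(adj, index=p.index, name="padj")
    family = pd.Series(family, index=p.index)
    out = pd.Series(np.nan, index=p.index, name="padj")
    for _, idx in p.groupby(family).groups.items():
        out.loc[idx] = multipletests(p.loc[idx].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Stage-level orchestration
# ---------------------------------------------------------------------------


def replicate_groups(
    descriptors: Sequence[SampleDescriptor],
    stage: str | None = None,
    include_hybrid_total: bool = False,
) -> dict[str, list[str]]:
    """Primitive replicate groups: parent totals plus hybrid allele columns.

    Hybrid total columns are sums of the two allele draws, so their
    count-level dispersion differs from the primitive groups; they are
    excluded from dispersion pooling by default.
    """
    groups: dict[str, list[str]] = {}
    for d in descriptors:
        if stage is not None and d.stage != stage:
            continue
        if d.cross == CROSS_HYBRID:
            if d.allele == ALLELE_TOTAL and not include_hybrid_total:
                continue
            key = f"{d.stage}.hybrid_{d.allele}"
        else:
            key = f"{d.stage}.{d.cross}"
        groups.setdefault(key, []).append(d.sample_id)
    return groups


def _stage_samples(
    descriptors: Sequence[SampleDescriptor], stage: str, cross: str, allele: str
) -> list[str]:
    return [
        d.sample_id
        for d in descriptors
        if d.stage == stage and d.cross == cross and d.allele == allele
    ]


def stage_contrasts(
    cm: CountMatrix,
    descriptors: Sequence[SampleDescriptor],
    stage: str,
    dispersion: pd.Series,
    pseudocount: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """All five per-stage contrasts (P, H, M, F, T), BH-adjusted per contrast.

    Hybrid total columns are used against the parental totals (M, F);
    allele columns feed only the allelic contrast (H) and hence the
    ratio-divergence test (T).
    """
    mat = _stage_samples(descriptors, stage, CROSS_MATERNAL, ALLELE_TOTAL)
    pat = _stage_samples(descriptors, stage, CROSS_PATERNAL, ALLELE_TOTAL)
    hyb_tot = _stage_samples(descriptors, stage, CROSS_HYBRID, ALLELE_TOTAL)
    hyb_m = _stage_samples(descriptors, stage, CROSS_HYBRID, ALLELE_MATERNAL)
    hyb_p = _stage_samples(descriptors, stage, CROSS_HYBRID, ALLELE_PATERNAL)

    res = {
        CONTRAST_PARENTS: wald_test(
            cm, mat, pat, dispersion, CONTRAST_PARENTS, pseudocount, stage
        ),
        CONTRAST_HYBRID_ALLELES: wald_test(
            cm, hyb_m, hyb_p, dispersion, CONTRAST_HYBRID_ALLELES, pseudocount, stage
        ),
        CONTRAST_VS_MATERNAL: wald_test(
            cm, hyb_tot, mat, dispersion, CONTRAST_VS_MATERNAL, pseudocount, stage
        ),
        CONTRAST_VS_PATERNAL: wald_test(
            cm, hyb_tot, pat, dispersion, CONTRAST_VS_PATERNAL, pseudocount, stage
        ),
    }
    res[CONTRAST_RATIO_DIVERGENCE] = ratio_divergence_test(
        res[CONTRAST_PARENTS], res[CONTRAST_HYBRID_ALLELES]
    )
    for name, frame in res.items():
        frame["padj"] = bh_adjust(frame["p"])
    return res
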