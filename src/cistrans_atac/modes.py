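"""Inheritance-mode and regulatory-mode classification of peaks.

Per peak and stage, five test results feed the decision tables:

* P — parental totals contrast (maternal species vs paternal species)
* H — hybrid allelic contrast (maternal vs paternal allele)
* M — hybrid total vs maternal-species total
* F — hybrid total vs paternal-species total
* T — ratio-divergence (L_P vs L_H)

Inheritance mode relates the hybrid's total signal to the two parents
(dominance geometry); regulatory mode attributes the between-species
divergence to local (cis) or diffusible (trans) influences through the
hybrid's allelic imbalance.  The evolutionary effect size is the log2
ratio of the two same-species accessibilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ALLELE_MATERNAL,
    ALLELE_PATERNAL,
    ALLELE_TOTAL,
    CROSS_HYBRID,
    CROSS_MATERNAL,
    CROSS_PATERNAL,
    INHERITANCE_CALLS,
    REGULATORY_CALLS,
    CountMatrix,
    SampleDescriptor,
)
from .differential import (
    CONTRAST_HYBRID_ALLELES,
    CONTRAST_PARENTS,
    CONTRAST_RATIO_DIVERGENCE,
    CONTRAST_VS_MATERNAL,
    CONTRAST_VS_PATERNAL,
    estimate_dispersion,
    moderate_dispersion,
    replicate_groups,
    stage_contrasts,
)

__all__ = [
    "classify_inheritance",
    "classify_regulatory",
    "effect_size",
    "classify_all",
    "count_mode_switches",
    "rank_by_effect",
    "mode_tallies",
]


def classify_inheritance(
    p_sig: np.ndarray,
    m_sig: np.ndarray,
    f_sig: np.ndarray,
    mean_maternal: np.ndarray,
    mean_paternal: np.ndarray,
    mean_hybrid: np.ndarray,
) -> np.ndarray:
    """Vectorized inheritance-mode decision table.

    ==================  =========================================================
    call                condition
    ==================  =========================================================
    conserved           none of P, M, F significant
    maternal_dominant   P and F significant, M not (hybrid tracks the mother)
    paternal_dominant   P and M significant, F not (hybrid tracks the father)
    additive            P, M, F all significant, hybrid strictly between parents
    overdominant        M and F significant, hybrid above both parents
    underdominant       M and F significant, hybrid below both parents
    ambiguous           anything else (including exact mean ties)
    ==================  =========================================================
    """
    p_sig, m_sig, f_sig = map(np.asarray, (p_sig, m_sig, f_sig))
    lo = np.minimum(mean_maternal, mean_paternal)
    hi = np.maximum(mean_maternal, mean_paternal)
    between = (mean_hybrid > lo) & (mean_hybrid < hi)
    above = mean_hybrid > hi
    below = mean_hybrid < lo
    conditions = [
        ~p_sig & ~m_sig & ~f_sig,
        p_sig & f_sig & ~m_sig,
        p_sig & m_sig & ~f_sig,
        m_sig & f_sig & above,
        m_sig & f_sig & below,
        p_sig & m_sig & f_sig & between,
    ]
    choices = [
        "conserved",
        "maternal_dominant",
        "paternal_dominant",
        "overdominant",
        "underdominant",
        "additive",
    ]
    return np.select(conditions, choices, default="ambiguous")


def classify_regulatory(
    p_sig: np.ndarray,
    h_sig: np.ndarray,
    t_sig: np.ndarray,
    l_p: np.ndarray,
    l_h: np.ndarray,
    require_parental_sig: bool = True,
) -> np.ndarray:
    """Vectorized regulatory-mode decision table.

    ==============  ============================================================
    call            condition (significance of P, H, T; signs of L_H, L_P - L_H)
    ==============  ============================================================
    conserved       P, H, T all not significant
    cis             P and H significant, T not — allelic imbalance reproduces
                    the parental difference in the common nuclear environment
    trans           P and T significant, H not — alleles equalize in the hybrid
                    while the parents differ
    cis_plus_trans  P, H, T significant and sign(L_H) == sign(L_P - L_H)
    cis_x_trans     P, H, T significant and the signs oppose
    compensatory    H and T significant, P not — imbalanced alleles whose
                    effects cancel between species
    ambiguous       anything else (including exact zero components)
    ==============  ============================================================

    With ``require_parental_sig=False`` the cis and trans rows drop their P
    condition (the allelic pattern alone decides).
    """
    p_sig, h_sig, t_sig = map(np.asarray, (p_sig, h_sig, t_sig))
    trans_component = np.asarray(l_p) - np.asarray(l_h)
    sh = np.sign(l_h)
    st = np.sign(trans_component)
    same_sign = (sh == st) & (sh != 0)
    opposite = (sh != st) & (sh != 0) & (st != 0)

    if require_parental_sig:
        cis = p_sig & h_sig & ~t_sig
        trans = p_sig & ~h_sig & t_sig
        interaction = p_sig & h_sig & t_sig
    else:
        cis = h_sig & ~t_sig
        trans = ~h_sig & t_sig
        interaction = h_sig & t_sig & p_sig
    conditions = [
        ~p_sig & ~h_sig & ~t_sig,
        cis,
        trans,
        ~p_sig & h_sig & t_sig,
        interaction & same_sign,
        interaction & opposite,
    ]
    choices = [
        "conserved",
        "cis",
        "trans",
        "compensatory",
        "cis_plus_trans",
        "cis_x_trans",
    ]
    return np.select(conditions, choices, default="ambiguous")


def effect_size(
    mean_maternal: np.ndarray, mean_paternal: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """Evolutionary effect size: log2 ratio of same-species accessibilities."""
    mean_maternal = np.asarray(mean_maternal, dtype=float)
    mean_paternal = np.asarray(mean_paternal, dtype=float)
    if (mean_maternal < 0).any() or (mean_paternal < 0).any():
        raise ValueError("group means must be nonnegative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2((mean_maternal + pseudocount) / (mean_paternal + pseudocount))


@dataclass
class ClassifyConfig:
    alpha: float = 0.05
    use_adjusted_p: bool = True
    pseudocount: float = 0.5
    require_parental_sig: bool = True
    pool_dispersion_across_stages: bool = True
    dispersion_moderation_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def _stage_order(descriptors: Sequence[SampleDescriptor]) -> list[str]:
    seen: list[str] = []
    for d in descriptors:
        if d.stage not in seen:
            seen.append(d.stage)
    return seen


def classify_all(
    cm: CountMatrix,
    descriptors: Sequence[SampleDescriptor],
    config: ClassifyConfig | None = None,
) -> pd.DataFrame:
    """One mode call per (retained peak, stage).

    Returns a long table with inheritance and regulatory calls, the effect
    size, the five adjusted p-values and the two log2 ratios they were
    derived from.  Requires size factors to be set on ``cm``.
    """
    config = config or ClassifyConfig()
    stages = _stage_order(descriptors)
    norm = cm.normalized()

    if config.pool_dispersion_across_stages:
        # effects are per-stage-constant in the model; replicate groups from
        # every stage share information for a steadier per-peak estimate
        pooled = moderate_dispersion(
            estimate_dispersion(cm, replicate_groups(descriptors)),
            config.dispersion_moderation_weight,
        )
    else:
        pooled = None

    frames = []
    for stage in stages:
        dispersion = (
            pooled
            if pooled is not None
            else moderate_dispersion(
                estimate_dispersion(cm, replicate_groups(descriptors, stage)),
                config.dispersion_moderation_weight,
            )
        )
        res = stage_contrasts(cm, descriptors, stage, dispersion, config.pseudocount)

        def sig(name: str) -> np.ndarray:
            col = "padj" if config.use_adjusted_p else "p"
            return (res[name][col] <= config.alpha).to_numpy()

        def cols(stage_: str, cross: str, allele: str) -> list[str]:
            return [
                d.sample_id
                for d in descriptors
                if d.stage == stage_ and d.cross == cross and d.allele == allele
            ]

        mean_mat = norm[cols(stage, CROSS_MATERNAL, ALLELE_TOTAL)].mean(axis=1).to_numpy()
        mean_pat = norm[cols(stage, CROSS_PATERNAL, ALLELE_TOTAL)].mean(axis=1).to_numpy()
        mean_hyb = norm[cols(stage, CROSS_HYBRID, ALLELE_TOTAL)].mean(axis=1).to_numpy()

        inheritance = classify_inheritance(
            sig(CONTRAST_PARENTS),
            sig(CONTRAST_VS_MATERNAL),
            sig(CONTRAST_VS_PATERNAL),
            mean_mat,
            mean_pat,
            mean_hyb,
        )
        l_p = res[CONTRAST_PARENTS]["log2_ratio"].to_numpy()
        l_h = res[CONTRAST_HYBRID_ALLELES]["log2_ratio"].to_numpy()
        regulatory = classify_regulatory(
            sig(CONTRAST_PARENTS),
            sig(CONTRAST_HYBRID_ALLELES),
            sig(CONTRAST_RATIO_DIVERGENCE),
            l_p,
            l_h,
            config.require_parental_sig,
        )
        frames.append(
            pd.DataFrame(
                {
                    "peak_id": cm.peak_ids,
                    "stage": stage,
                    "inheritance_mode": inheritance,
                    "regulatory_mode": regulatory,
                    "effect_size": effect_size(mean_mat, mean_pat, config.pseudocount),
                    "L_P": l_p,
                    "L_H": l_h,
                    "padj_P": res[CONTRAST_PARENTS]["padj"].to_numpy(),
                    "padj_H": res[CONTRAST_HYBRID_ALLELES]["padj"].to_numpy(),
                    "padj_M": res[CONTRAST_VS_MATERNAL]["padj"].to_numpy(),
                    "padj_F": res[CONTRAST_VS_PATERNAL]["padj"].to_numpy(),
                    "padj_T": res[CONTRAST_RATIO_DIVERGENCE]["padj"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def mode_tallies(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per mode per stage, both classifications."""
    rows = []
    for stage, sub in calls.groupby("stage", sort=False):
        n = len(sub)
        for kind, vocab in (
            ("inheritance", INHERITANCE_CALLS),
            ("regulatory", REGULATORY_CALLS),
        ):
            col = f"{kind}_mode"
            vc = sub[col].value_counts()
            for mode in vocab:
                count = int(vc.get(mode, 0))
                rows.append((stage, kind, mode, count, count / n if n else 0.0))
    return pd.DataFrame(
        rows, columns=["stage", "classification", "mode", "count", "proportion"]
    )


def count_mode_switches(
    calls: pd.DataFrame, which: str = "regulatory"
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-peak switch counts between consecutive stages plus the transition
    matrix summed over consecutive stage pairs."""
    col = f"{which}_mode"
    if col not in calls.columns:
        raise ValueError(f"unknown classification {which!r}")
    stages = list(dict.fromkeys(calls["stage"]))
    if len(stages) < 2:
        raise ValueError("mode switching needs at least 2 stages")
    wide = calls.pivot(index="peak_id", columns="stage", values=col)[stages]
    vocab = INHERITANCE_CALLS if which == "inheritance" else REGULATORY_CALLS
    matrix = pd.DataFrame(0, index=list(vocab), columns=list(vocab), dtype=int)
    switches = pd.Series(0, index=wide.index, dtype=int)
    for a, b in zip(stages[:-1], stages[1:]):
        pair = wide[[a, b]].dropna()
        switches = switches.add((pair[a] != pair[b]).astype(int), fill_value=0)
        tab = pd.crosstab(pair[a], pair[b])
        matrix = matrix.add(tab.reindex(index=vocab, columns=vocab, fill_value=0), fill_value=0)
    return switches.astype(int), matrix.astype(int)


def rank_by_effect(calls: pd.DataFrame, k: int, stage: str | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """Top-k peaks by |effect size| with regulatory-mode fractions among them.

    Descending |ES|; exact ties broken by lexicographically smaller peak_id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    sub = calls if stage is None else calls[calls["stage"] == stage]
    if k > len(sub):
        raise ValueError(f"k={k} exceeds the {len(sub)} available peaks")
    ranked = sub.assign(abs_es=sub["effect_size"].abs()).sort_values(
        ["abs_es", "peak_id"], ascending=[False, True], kind="stable"
    )
    top = ranked.head(k).drop(columns="abs_es")
    fractions = (
        top["regulatory_mode"].value_counts(normalize=True)
        .reindex(REGULATORY_CALLS, fill_value=0.0)
    )
    return top, fractions
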