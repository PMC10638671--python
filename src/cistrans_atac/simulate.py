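"""Synthetic allele-specific ATAC-seq count data with known ground truth.

The generator emulates the downstream count structure of a hybrid
chromatin-accessibility study: two same-species crosses and one F1 hybrid
cross sampled at several developmental stages with replicate libraries,
hybrid columns split by parent-of-origin allele, and negative-binomial
read-count noise.

Mean model per peak (baseline mean mu, cis effect c, trans effect t, trans
dominance d, all effects log2):

=====================  =============================
group                  expected normalized mean
=====================  =============================
maternal-species total ``mu * 2**(c + t)``
paternal-species total ``mu``
hybrid maternal allele ``(mu / 2) * 2**(c + d * t)``
hybrid paternal allele ``(mu / 2) * 2**(d * t)``
hybrid total           sum of its two allele columns
=====================  =============================

The hybrid total column is the exact sum of the two allele draws (both
alleles share one library), never an independent draw.  Counts are drawn
``NB(mean * library_multiplier, dispersion)`` with variance
``m + dispersion * m**2``.
"""

from __future__ import annotations

import math
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
    DEFAULT_STAGES,
    DISTAL_BP,
    PROXIMAL_BP,
    CountMatrix,
    GeneModel,
    PeakInterval,
    SampleDescriptor,
    TruthRecord,
    make_sample_id,
    REGULATORY_MODES,
)

__all__ = [
    "SimulationDesign",
    "make_truth",
    "simulate_counts",
    "make_annotation",
    "simulate_expression_table",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Layout of a simulated experiment.

    ``mean_depth_scale`` is either a single multiplier applied to every
    library or a mapping from sample_id to a per-library multiplier
    (unlisted samples default to 1.0).  ``stage_effects`` optionally scales
    the cis/trans effects per stage, e.g. ``{"larva": (1.0, 0.0)}`` switches
    the trans effect off at larva for mode-switch testing; effects are
    per-stage-constant by default.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_cross: int = 3
    mean_depth_scale: float | Mapping[str, float] = 1.0
    seed: int = 0
    coupling_odds: float = 1.0
    stage_effects: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("at least one stage required")
        if self.replicates_per_cross < 2:
            raise ValueError(
                f"replicates_per_cross must be >= 2 so variances are estimable, "
                f"got {self.replicates_per_cross}"
            )
        if self.coupling_odds <= 0:
            raise ValueError("coupling_odds must be positive")
        if isinstance(self.mean_depth_scale, Mapping):
            bad = {k: v for k, v in self.mean_depth_scale.items() if v <= 0}
            if bad:
                raise ValueError(f"library multipliers must be > 0, got {bad}")
        elif self.mean_depth_scale <= 0:
            raise ValueError("mean_depth_scale must be > 0")

    def depth_multiplier(self, sample_id: str) -> float:
        if isinstance(self.mean_depth_scale, Mapping):
            return float(self.mean_depth_scale.get(sample_id, 1.0))
        return float(self.mean_depth_scale)

    def effect_scale(self, stage: str) -> tuple[float, float]:
        if self.stage_effects is None:
            return (1.0, 1.0)
        c, t = self.stage_effects.get(stage, (1.0, 1.0))
        return (float(c), float(t))


# ---------------------------------------------------------------------------
# Effect-size laws
# ---------------------------------------------------------------------------

Law = float | tuple


def _draw_magnitudes(law: Law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n positive effect magnitudes from a small family of laws.

    ``law`` may be a scalar (degenerate/fixed law), or a tuple:
    ``("fixed", v)``, ``("uniform", lo, hi)``, ``("lognormal", mean, sigma)``
    (parameters of the underlying normal on the natural-log scale), or
    ``("exponential", scale)``.
    """
    if isinstance(law, (int, float)):
        return np.full(n, float(law))
    name = law[0]
    if name == "fixed":
        return np.full(n, float(law[1]))
    if name == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not 0 <= lo <= hi:
            raise ValueError(f"uniform law needs 0 <= lo <= hi, got ({lo}, {hi})")
        return rng.uniform(lo, hi, size=n)
    if name == "lognormal":
        return rng.lognormal(float(law[1]), float(law[2]), size=n)
    if name == "exponential":
        return rng.exponential(float(law[1]), size=n)
    raise ValueError(f"unknown effect-size law {law!r}")


def _largest_remainder(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Deterministic apportionment of n items to classes by largest remainder."""
    keys = list(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    # ties broken by vocabulary order for determinism
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), keys.index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


def make_truth(
    n_peaks: int,
    mode_proportions: Mapping[str, float],
    effect_size_law: Law | Mapping[str, Law] = 1.5,
    seed: int = 0,
    *,
    baseline_mean: Law = 300.0,
    dispersion: float = 0.05,
    trans_dominance: float = 0.5,
    cx_trans_ratio: float = 2.0,
) -> list[TruthRecord]:
    """Generate per-peak ground-truth regulatory parameters.

    Class counts follow ``mode_proportions`` after deterministic
    largest-remainder rounding.  ``effect_size_law`` gives the law of the
    effect magnitudes |c| and |t|; pass a mapping with keys ``"cis"`` and
    ``"trans"`` to use different laws for the two effects.

    For the opposite-sign interaction class (``cis_x_trans``) the trans
    magnitude is scaled by ``cx_trans_ratio`` so the class stays distinct
    from ``compensatory``, which is defined by exact cancellation c = -t.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    unknown = set(mode_proportions) - set(REGULATORY_MODES)
    if unknown:
        raise ValueError(f"unknown regulatory mode(s): {sorted(unknown)}")
    total = sum(mode_proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode proportions must sum to 1, got {total!r}")
    if cx_trans_ratio == 1.0:
        raise ValueError(
            "cx_trans_ratio must differ from 1: with |t| = |c| the "
            "opposite-sign interaction collapses onto the compensatory class"
        )

    if isinstance(effect_size_law, Mapping):
        cis_law = effect_size_law.get("cis", 1.5)
        trans_law = effect_size_law.get("trans", 1.5)
    else:
        cis_law = trans_law = effect_size_law

    rng = np.random.default_rng(seed)
    counts = _largest_remainder(n_peaks, mode_proportions)
    width = max(4, len(str(n_peaks)))

    records: list[TruthRecord] = []
    idx = 0
    for mode in REGULATORY_MODES:
        k = counts.get(mode, 0)
        if k == 0:
            continue
        mags_c = _draw_magnitudes(cis_law, k, rng)
        mags_t = _draw_magnitudes(trans_law, k, rng)
        signs_c = rng.choice([-1.0, 1.0], size=k)
        signs_t = rng.choice([-1.0, 1.0], size=k)
        mus = _draw_magnitudes(baseline_mean, k, rng)
        for j in range(k):
            if mode == "conserved":
                c, t = 0.0, 0.0
            elif mode == "cis":
                c, t = signs_c[j] * mags_c[j], 0.0
            elif mode == "trans":
                c, t = 0.0, signs_t[j] * mags_t[j]
            elif mode == "cis_plus_trans":
                c = signs_c[j] * mags_c[j]
                t = signs_c[j] * mags_t[j]
            elif mode == "compensatory":
                c = signs_c[j] * mags_c[j]
                t = -c
            else:  # cis_x_trans
                c = signs_c[j] * mags_c[j]
                t = -signs_c[j] * cx_trans_ratio * mags_t[j]
            records.append(
                TruthRecord(
                    peak_id=f"peak_{idx:0{width}d}",
                    baseline_mean=float(mus[j]),
                    cis_shift=float(c),
                    trans_shift=float(t),
                    trans_dominance=float(trans_dominance),
                    dispersion=float(dispersion),
                    true_regulatory_mode=mode,
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB draw with variance m + dispersion * m**2 (Poisson when tiny)."""
    mean = np.asarray(mean, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = dispersion < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        size = dispersion[~tiny]
        r = 1.0 / size
        p = r / (r + mean[~tiny])
        out[~tiny] = rng.negative_binomial(r, p)
    return out


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [t.peak_id for t in truth],
            "baseline_mean": [t.baseline_mean for t in truth],
            "cis_shift": [t.cis_shift for t in truth],
            "trans_shift": [t.trans_shift for t in truth],
            "trans_dominance": [t.trans_dominance for t in truth],
            "dispersion": [t.dispersion for t in truth],
            "true_regulatory_mode": [t.true_regulatory_mode for t in truth],
        }
    ).set_index("peak_id", drop=False)


def expected_group_means(
    truth: Sequence[TruthRecord], stage_effect: tuple[float, float] = (1.0, 1.0)
) -> pd.DataFrame:
    """Expected normalized means per peak for the four primitive groups."""
    tf = truth_to_frame(truth)
    mu = tf["baseline_mean"].to_numpy()
    c = tf["cis_shift"].to_numpy() * stage_effect[0]
    t = tf["trans_shift"].to_numpy() * stage_effect[1]
    d = tf["trans_dominance"].to_numpy()
    return pd.DataFrame(
        {
            "maternal_total": mu * 2.0 ** (c + t),
            "paternal_total": mu,
            "hybrid_maternal_allele": (mu / 2.0) * 2.0 ** (c + d * t),
            "hybrid_paternal_allele": (mu / 2.0) * 2.0 ** (d * t),
        },
        index=tf.index,
    )


def simulate_counts(
    truth: Sequence[TruthRecord], design: SimulationDesign
) -> tuple[CountMatrix, list[SampleDescriptor]]:
    """Draw an allele-specific count matrix under the hybrid mean model.

    Column order is deterministic (stage-major, then cross, then replicate;
    hybrid replicates contribute maternal-allele, paternal-allele and total
    columns, the total being the exact sum of its two allele draws), and a
    fixed ``design.seed`` yields bit-identical output.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("truth must be nonempty")
    rng = np.random.default_rng(design.seed)
    disp = np.array([t.dispersion for t in truth])
    peak_ids = [t.peak_id for t in truth]

    descriptors: list[SampleDescriptor] = []
    columns: dict[str, np.ndarray] = {}

    for stage in design.stages:
        means = expected_group_means(truth, design.effect_scale(stage))
        for rep in range(1, design.replicates_per_cross + 1):
            for cross in (CROSS_MATERNAL, CROSS_PATERNAL):
                sid = make_sample_id(cross, stage, rep)
                base = (
                    means["maternal_total"]
                    if cross == CROSS_MATERNAL
                    else means["paternal_total"]
                ).to_numpy()
                columns[sid] = _nb_draw(rng, base * design.depth_multiplier(sid), disp)
                descriptors.append(SampleDescriptor(sid, cross, stage, rep))
            sid_m = make_sample_id(CROSS_HYBRID, stage, rep, ALLELE_MATERNAL)
            sid_p = make_sample_id(CROSS_HYBRID, stage, rep, ALLELE_PATERNAL)
            sid_t = make_sample_id(CROSS_HYBRID, stage, rep, ALLELE_TOTAL)
            # both alleles share one library: one multiplier for all three
            mult = design.depth_multiplier(sid_t)
            col_m = _nb_draw(
                rng, means["hybrid_maternal_allele"].to_numpy() * mult, disp
            )
            col_p = _nb_draw(
                rng, means["hybrid_paternal_allele"].to_numpy() * mult, disp
            )
            columns[sid_m] = col_m
            columns[sid_p] = col_p
            columns[sid_t] = col_m + col_p  # identity, not a new draw
            descriptors.append(
                SampleDescriptor(sid_m, CROSS_HYBRID, stage, rep, ALLELE_MATERNAL)
            )
            descriptors.append(
                SampleDescriptor(sid_p, CROSS_HYBRID, stage, rep, ALLELE_PATERNAL)
            )
            descriptors.append(
                SampleDescriptor(sid_t, CROSS_HYBRID, stage, rep, ALLELE_TOTAL)
            )

    counts = pd.DataFrame(columns, index=pd.Index(peak_ids, name="peak_id"))
    counts = counts[[d.sample_id for d in descriptors]]
    return CountMatrix(counts), descriptors


# ---------------------------------------------------------------------------
# Annotation: genes, peak intervals, peak-gene distances
# ---------------------------------------------------------------------------

_STRATA_RANGES = {
    "proximal": (0, PROXIMAL_BP),
    "distal": (PROXIMAL_BP + 1, DISTAL_BP),
    "beyond": (DISTAL_BP + 1, 4 * DISTAL_BP),
}


def make_annotation(
    n_genes: int,
    chrom_length: int,
    truth: Sequence[TruthRecord],
    placement: Mapping[str, float] | None = None,
    grn_fraction: float = 0.1,
    tf_fraction: float = 0.3,
    seed: int = 0,
    *,
    chrom: str = "chr1",
    peak_width: tuple[int, int] = (200, 600),
    grn_peak_weight: float = 1.0,
) -> tuple[list[GeneModel], list[PeakInterval], pd.DataFrame]:
    """Place genes and peaks on one synthetic chromosome.

    Each peak targets a gene and is placed at a controlled center-to-TLS
    distance drawn from one of three strata (proximal <=500 bp, distal
    501-25,000 bp, beyond >25,000 bp); ``placement`` gives the stratum
    fractions (default 1/3 each, largest-remainder rounded).
    ``grn_peak_weight`` > 1 makes peaks target GRN genes preferentially,
    producing elevated peak density near those genes.

    Returns (genes, peak intervals, distance table).  The distance table
    holds every peak-gene pair with center-to-TLS distance <= 25 kb plus
    each peak's target pair, and is the geometry input for the expression
    simulator.
    """
    truth = list(truth)
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not truth:
        raise ValueError("truth must be nonempty")
    if not 0 <= grn_fraction <= tf_fraction <= 1:
        raise ValueError(
            "need 0 <= grn_fraction <= tf_fraction <= 1 "
            "(GRN genes are a subset of transcription factors)"
        )
    placement = dict(placement or {"proximal": 1 / 3, "distal": 1 / 3, "beyond": 1 / 3})
    unknown = set(placement) - set(_STRATA_RANGES)
    if unknown:
        raise ValueError(f"unknown placement strata: {sorted(unknown)}")
    psum = sum(placement.values())
    if abs(psum - 1.0) > 1e-9:
        raise ValueError(f"placement fractions must sum to 1, got {psum!r}")

    max_dist = max(
        _STRATA_RANGES[s][1] for s, f in placement.items() if f > 0
    )
    margin = max_dist + peak_width[1]
    if chrom_length <= 2 * margin:
        raise ValueError(
            f"stratum quotas exceed chromosome capacity: need length > "
            f"{2 * margin}, got {chrom_length}"
        )

    rng = np.random.default_rng(seed)
    gwidth = max(4, len(str(n_genes)))
    tls = np.sort(rng.integers(margin, chrom_length - margin, size=n_genes))
    strands = rng.choice(["+", "-"], size=n_genes)
    n_tf = int(round(tf_fraction * n_genes))
    n_grn = int(round(grn_fraction * n_genes))
    tf_idx = rng.choice(n_genes, size=n_tf, replace=False)
    grn_idx = rng.choice(tf_idx, size=n_grn, replace=False) if n_tf else np.array([], int)
    is_tf = np.zeros(n_genes, bool)
    is_tf[tf_idx] = True
    is_grn = np.zeros(n_genes, bool)
    is_grn[grn_idx] = True
    genes = [
        GeneModel(
            gene_id=f"gene_{i:0{gwidth}d}",
            chrom=chrom,
            tls=int(tls[i]),
            strand=str(strands[i]),
            is_tf=bool(is_tf[i]),
            is_grn=bool(is_grn[i]),
        )
        for i in range(n_genes)
    ]

    # stratum per peak: largest-remainder quotas, then shuffled so distance
    # category is independent of the (mode-blocked) truth order
    n_peaks = len(truth)
    quota = _largest_remainder(n_peaks, placement)
    strata_arr: list[str] = []
    for s in ("proximal", "distal", "beyond"):
        strata_arr.extend([s] * quota.get(s, 0))
    strata = [strata_arr[i] for i in rng.permutation(n_peaks)]

    weights = np.where(is_grn, grn_peak_weight, 1.0)
    weights = weights / weights.sum()
    target_idx = rng.choice(n_genes, size=n_peaks, p=weights)

    peaks: list[PeakInterval] = []
    target_rows = []
    for i, rec in enumerate(truth):
        lo, hi = _STRATA_RANGES[strata[i]]
        dist = int(rng.integers(lo, hi + 1))
        side = int(rng.choice([-1, 1]))
        g = int(target_idx[i])
        center = int(tls[g]) + side * dist
        if not 0 <= center < chrom_length:
            center = int(tls[g]) - side * dist
        width = int(rng.integers(peak_width[0], peak_width[1] + 1))
        # keep the intended center (distance stratum) exact
        start = center - width // 2
        end = start + width
        if start < 0 or end > chrom_length:
            raise ValueError(
                "stratum quotas exceed chromosome capacity near the boundary"
            )
        peaks.append(PeakInterval(chrom, start, end, rec.peak_id))
        target_rows.append((rec.peak_id, genes[g].gene_id, dist, True))

    # all pairs within the 25-kb window (for exposure computation)
    centers = np.array([p.center for p in peaks])
    order = np.argsort(centers)
    rows = list(target_rows)
    seen = {(r[0], r[1]) for r in target_rows}
    sorted_centers = centers[order]
    for gi, gene in enumerate(genes):
        lo = np.searchsorted(sorted_centers, gene.tls - DISTAL_BP, side="left")
        hi = np.searchsorted(sorted_centers, gene.tls + DISTAL_BP, side="right")
        for k in order[lo:hi]:
            pid = peaks[int(k)].peak_id
            if (pid, gene.gene_id) in seen:
                continue
            rows.append(
                (pid, gene.gene_id, abs(int(centers[int(k)]) - gene.tls), False)
            )
    distances = pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "distance", "is_target"]
    ).sort_values(["peak_id", "gene_id"], kind="stable").reset_index(drop=True)
    return genes, peaks, distances


# ---------------------------------------------------------------------------
# Matched gene-expression table
# ---------------------------------------------------------------------------


def simulate_expression_table(
    genes: Sequence[GeneModel],
    peak_truth: Sequence[TruthRecord],
    distances: pd.DataFrame,
    coupling_odds: float,
    seed: int = 0,
    *,
    base_de_rate: float = 0.2,
    base_cis_fraction: float = 0.5,
    stages: Sequence[str] = DEFAULT_STAGES,
    window: int = DISTAL_BP,
) -> pd.DataFrame:
    """Emulate a companion transcriptome study's per-gene DE calls.

    A gene is "exposed" when at least one truly non-conserved peak lies
    within ``window`` bp of its TLS.  DE status is Bernoulli with base rate
    ``base_de_rate`` for unexposed genes; for exposed genes the odds are
    multiplied by ``coupling_odds``.  Among DE genes the expression
    regulatory mode is cis with base probability ``base_cis_fraction``,
    with the same odds multiplier applied for exposed genes so that
    cis-based differential expression is preferentially found near truly
    divergent peaks.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be nonempty")
    if coupling_odds <= 0:
        raise ValueError("coupling_odds must be positive")
    if not 0 < base_de_rate < 1:
        raise ValueError("base_de_rate must lie in (0, 1)")

    truth_frame = truth_to_frame(list(peak_truth))
    nonconserved = set(
        truth_frame.loc[
            truth_frame["true_regulatory_mode"] != "conserved", "peak_id"
        ]
    )
    near = distances[distances["distance"] <= window]
    exposed_genes = set(near.loc[near["peak_id"].isin(nonconserved), "gene_id"])

    def odds_to_p(odds: float) -> float:
        return odds / (1.0 + odds)

    base_odds = base_de_rate / (1.0 - base_de_rate)
    p_exposed = odds_to_p(base_odds * coupling_odds)
    cis_odds = base_cis_fraction / (1.0 - base_cis_fraction) if base_cis_fraction < 1 else np.inf
    p_cis_exposed = odds_to_p(cis_odds * coupling_odds)

    rng = np.random.default_rng(seed)
    rows = []
    for stage in stages:
        for g in genes:
            exposed = g.gene_id in exposed_genes
            p_de = p_exposed if exposed else base_de_rate
            de = bool(rng.random() < p_de)
            if de:
                p_cis = p_cis_exposed if exposed else base_cis_fraction
                mode = "cis" if rng.random() < p_cis else "trans"
            else:
                mode = "conserved"
            rows.append((g.gene_id, stage, int(de), mode))
    return pd.DataFrame(
        rows, columns=["gene_id", "stage", "de_status", "expr_mode"]
    )
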