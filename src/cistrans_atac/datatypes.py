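"""Core domain types shared across the package.

The analyzed unit throughout is a peak-by-sample matrix of nonnegative
integer ATAC-seq read counts.  Columns are identified by a
:class:`SampleDescriptor` (cross x stage x replicate x allele-of-origin),
rows by a :class:`PeakInterval`.  The synthetic generator attaches a
:class:`TruthRecord` per peak describing the generating cis (``c``) and
trans (``t``) effects on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Closed vocabularies -------------------------------------------------------

CROSS_MATERNAL = "maternal_species"
CROSS_PATERNAL = "paternal_species"
CROSS_HYBRID = "hybrid"
CROSSES = (CROSS_MATERNAL, CROSS_PATERNAL, CROSS_HYBRID)

ALLELE_TOTAL = "total"
ALLELE_MATERNAL = "maternal"
ALLELE_PATERNAL = "paternal"
ALLELES = (ALLELE_TOTAL, ALLELE_MATERNAL, ALLELE_PATERNAL)

#: Regulatory modes a peak's divergence can be generated by / classified as.
REGULATORY_MODES = (
    "conserved",
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_x_trans",
    "compensatory",
)
REGULATORY_CALLS = REGULATORY_MODES + ("ambiguous",)

#: Inheritance modes relate the hybrid's total signal to the two parents.
INHERITANCE_CALLS = (
    "conserved",
    "additive",
    "maternal_dominant",
    "paternal_dominant",
    "overdominant",
    "underdominant",
    "ambiguous",
)

DEFAULT_STAGES = ("blastula", "gastrula", "larva")

#: Distance strata relative to a gene's translation start site (TLS).
PROXIMAL_BP = 500
DISTAL_BP = 25_000
LINK_CATEGORIES = ("proximal", "distal", "beyond")


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


@dataclass(frozen=True)
class TruthRecord:
    """Generating parameters for one peak in the synthetic model.

    ``cis_shift`` (c) and ``trans_shift`` (t) are log2 effects; the
    maternal-species total mean is ``baseline_mean * 2**(c + t)`` while the
    paternal-species mean is ``baseline_mean``.  ``trans_dominance`` (d) is
    the fraction of the trans effect expressed in the shared hybrid nuclear
    environment; d=0.5 blends the parental trans factors evenly, d=1.0
    emulates full maternal trans dominance.
    """

    peak_id: str
    baseline_mean: float
    cis_shift: float
    trans_shift: float
    trans_dominance: float
    dispersion: float
    true_regulatory_mode: str

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be positive, got {self.baseline_mean}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be positive, got {self.dispersion}")
        if not 0.0 <= self.trans_dominance <= 1.0:
            raise ValueError(f"trans_dominance must lie in [0, 1], got {self.trans_dominance}")
        mode, c, t = self.true_regulatory_mode, self.cis_shift, self.trans_shift
        if mode not in REGULATORY_MODES:
            raise ValueError(f"unknown regulatory mode {mode!r}")
        ok = {
            "conserved": c == 0 and t == 0,
            "cis": c != 0 and t == 0,
            "trans": c == 0 and t != 0,
            "compensatory": c != 0 and c == -t,
            "cis_plus_trans": c != 0 and t != 0 and _sign(c) == _sign(t),
            "cis_x_trans": c != 0 and t != 0 and _sign(c) != _sign(t) and c != -t,
        }[mode]
        if not ok:
            raise ValueError(
                f"effects (c={c}, t={t}) violate the invariant of mode {mode!r}"
            )


@dataclass(frozen=True)
class SampleDescriptor:
    """Identity of one column of the count matrix."""

    sample_id: str
    cross: str
    stage: str
    replicate: int
    allele: str = ALLELE_TOTAL

    def __post_init__(self) -> None:
        if self.cross not in CROSSES:
            raise ValueError(f"unknown cross {self.cross!r}")
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele {self.allele!r}")
        if self.allele != ALLELE_TOTAL and self.cross != CROSS_HYBRID:
            raise ValueError(
                f"allele-of-origin columns only exist for hybrid samples "
                f"({self.sample_id}: cross={self.cross}, allele={self.allele})"
            )


def make_sample_id(cross: str, stage: str, replicate: int, allele: str = ALLELE_TOTAL) -> str:
    return f"{cross}.{stage}.r{replicate}.{allele}"


def descriptors_to_frame(descriptors: Iterable[SampleDescriptor]) -> pd.DataFrame:
    rows = [
        (d.sample_id, d.cross, d.stage, d.replicate, d.allele) for d in descriptors
    ]
    frame = pd.DataFrame(
        rows, columns=["sample_id", "cross", "stage", "replicate", "allele"]
    )
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    key = frame[["cross", "stage", "replicate", "allele"]]
    if key.duplicated().any():
        raise ValueError("duplicate (cross, stage, replicate, allele) combination")
    return frame.set_index("sample_id", drop=False)


def frame_to_descriptors(frame: pd.DataFrame) -> list[SampleDescriptor]:
    return [
        SampleDescriptor(
            sample_id=str(r.sample_id),
            cross=str(r.cross),
            stage=str(r.stage),
            replicate=int(r.replicate),
            allele=str(r.allele),
        )
        for r in frame.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PeakInterval:
    """A peak as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"degenerate interval {self.peak_id!r}: [{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its translation start site (TLS).

    The TLS, not the TSS, is the positional anchor because 5' UTR
    annotation is unreliable in the genomes this workflow targets.
    """

    gene_id: str
    chrom: str
    tls: int
    strand: str
    is_tf: bool = False
    is_grn: bool = False

    def __post_init__(self) -> None:
        if self.tls < 0:
            raise ValueError(f"tls must be >= 0, got {self.tls}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.is_grn and not self.is_tf:
            raise ValueError(
                f"{self.gene_id}: GRN genes must be flagged as transcription factors"
            )


class CountMatrix:
    """Peak-by-sample matrix of nonnegative integer read counts.

    ``size_factors`` are absent until computed by
    :func:`cistrans_atac.preprocess.size_factors`.
    """

    def __init__(self, counts: pd.DataFrame, size_factors: pd.Series | None = None):
        counts = counts.copy()
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                    raise ValueError(
                        f"non-integer count at peak {counts.index[bad[0]]!r}, "
                        f"sample {counts.columns[bad[1]]!r}"
                    )
                counts = counts.round().astype(np.int64)
            if (counts.to_numpy() < 0).any():
                bad = np.argwhere(counts.to_numpy() < 0)[0]
                raise ValueError(
                    f"negative count at peak {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
        if counts.index.duplicated().any():
            raise ValueError("duplicate peak_id in count matrix index")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample_id in count matrix columns")
        self.counts = counts
        if size_factors is not None:
            size_factors = size_factors.reindex(counts.columns)
            if size_factors.isna().any():
                missing = size_factors.index[size_factors.isna()][0]
                raise ValueError(f"size factor missing for sample {missing!r}")
            if (size_factors <= 0).any():
                raise ValueError("size factors must all be positive")
        self.size_factors = size_factors

    # -- basic accessors ----------------------------------------------------

    @property
    def peak_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors."""
        if self.size_factors is None:
            raise ValueError("size factors have not been computed yet")
        return self.counts / self.size_factors

    def subset_peaks(self, peak_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(peak_ids)], self.size_factors)

    def copy(self) -> "CountMatrix":
        sf = None if self.size_factors is None else self.size_factors.copy()
        return CountMatrix(self.counts.copy(), sf)

    def equals(self, other: "CountMatrix") -> bool:
        if not self.counts.equals(other.counts):
            return False
        if (self.size_factors is None) != (other.size_factors is None):
            return False
        if self.size_factors is not None and not np.allclose(
            self.size_factors, other.size_factors.reindex(self.size_factors.index)
        ):
            return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        sf = "set" if self.size_factors is not None else "unset"
        return f"CountMatrix({n} peaks x {m} samples, size_factors {sf})"


def link_category(distance: float) -> str:
    """Distance stratum of a peak-center-to-TLS distance in bp."""
    if distance <= PROXIMAL_BP:
        return "proximal"
    if distance <= DISTAL_BP:
        return "distal"
    return "beyond"
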