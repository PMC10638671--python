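"""Readers and writers for the package's plain-text interchange formats.

All tables are TSV with a header row; peak and read intervals are BED
(0-based, half-open), BED4 for peaks (name column carries the peak_id) and
BED3 or BED4 for reads.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    GeneModel,
    PeakInterval,
    SampleDescriptor,
    descriptors_to_frame,
    frame_to_descriptors,
)

__all__ = [
    "write_counts",
    "read_counts",
    "write_samples",
    "read_samples",
    "write_peaks_bed",
    "read_peaks_bed",
    "read_reads_bed",
    "write_genes",
    "read_genes",
    "write_expression",
    "read_expression",
    "write_truth",
    "read_truth",
    "read_inputs",
]


# -- counts -----------------------------------------------------------------


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    out = cm.counts.copy()
    out.index.name = "peak_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | os.PathLike) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="peak_id")
    arr = frame.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        for j, col in enumerate(frame.columns):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any():
                row = frame.index[coerced.isna()][0]
                raise ValueError(
                    f"non-integer count at row {row!r}, column {col!r} in {path}"
                )
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at row {frame.index[bad[0]]!r}, "
                f"column {frame.columns[bad[1]]!r} in {path}"
            )
    return CountMatrix(frame)


# -- sample descriptors -----------------------------------------------------

_SAMPLE_COLUMNS = ["sample_id", "cross", "stage", "replicate", "allele"]


def write_samples(descriptors: Sequence[SampleDescriptor], path: str | os.PathLike) -> None:
    descriptors_to_frame(descriptors).to_csv(path, sep="\t", index=False)


def read_samples(path: str | os.PathLike) -> list[SampleDescriptor]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_SAMPLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"samples table {path} lacks columns: {sorted(missing)}")
    return frame_to_descriptors(frame[_SAMPLE_COLUMNS])


# -- BED intervals ----------------------------------------------------------


def write_peaks_bed(peaks: Sequence[PeakInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def _parse_bed(path: str | os.PathLike, *, need_name: bool) -> list[PeakInterval]:
    out: list[PeakInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({line!r})")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates ({line!r})"
                ) from None
            if need_name and len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 name column required")
            name = fields[3] if len(fields) >= 4 else f"interval_{lineno}"
            try:
                out.append(PeakInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def read_peaks_bed(path: str | os.PathLike) -> list[PeakInterval]:
    peaks = _parse_bed(path, need_name=True)
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate peak_id {dup!r} in {path}")
    return peaks


def read_reads_bed(path: str | os.PathLike) -> list[PeakInterval]:
    return _parse_bed(path, need_name=False)


# -- genes ------------------------------------------------------------------

_GENE_COLUMNS = ["gene_id", "chrom", "tls", "strand", "is_tf", "is_grn"]


def write_genes(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [
            (g.gene_id, g.chrom, g.tls, g.strand, int(g.is_tf), int(g.is_grn))
            for g in genes
        ],
        columns=_GENE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_genes(path: str | os.PathLike) -> list[GeneModel]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = set(_GENE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"genes table {path} lacks columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=r.gene_id,
            chrom=r.chrom,
            tls=int(r.tls),
            strand=str(r.strand),
            is_tf=bool(r.is_tf),
            is_grn=bool(r.is_grn),
        )
        for r in frame.itertuples(index=False)
    ]


# -- expression and truth tables -------------------------------------------

_EXPR_COLUMNS = ["gene_id", "stage", "de_status", "expr_mode"]


def write_expression(expression: pd.DataFrame, path: str | os.PathLike) -> None:
    expression[_EXPR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "stage": str})
    missing = set(_EXPR_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"expression table {path} lacks columns: {sorted(missing)}")
    frame["de_status"] = frame["de_status"].astype(int)
    return frame[_EXPR_COLUMNS]


def write_truth(truth_frame: pd.DataFrame, path: str | os.PathLike) -> None:
    truth_frame.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"peak_id": str})
    return frame.set_index("peak_id", drop=False)


# -- bundled reader with referential-integrity checks -----------------------


def read_inputs(
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    peaks_path: str | os.PathLike,
    genes_path: str | os.PathLike | None = None,
    expression_path: str | os.PathLike | None = None,
) -> dict:
    """Read the full input set, verifying cross-file referential integrity.

    Every counts column must have a sample descriptor and every counts row a
    peak interval; violations raise with the offending identifier named.
    """
    cm = read_counts(counts_path)
    descriptors = read_samples(samples_path)
    peaks = read_peaks_bed(peaks_path)

    described = {d.sample_id for d in descriptors}
    for sid in cm.sample_ids:
        if sid not in described:
            raise ValueError(
                f"counts column {sid!r} has no descriptor in {samples_path}"
            )
    peak_ids = {p.peak_id for p in peaks}
    for pid in cm.peak_ids:
        if pid not in peak_ids:
            raise ValueError(f"counts row {pid!r} has no interval in {peaks_path}")

    out = {"counts": cm, "descriptors": descriptors, "peaks": peaks}
    if genes_path is not None:
        out["genes"] = read_genes(genes_path)
    if expression_path is not None:
        expression = read_expression(expression_path)
        if genes_path is not None:
            known = {g.gene_id for g in out["genes"]}
            orphan = set(expression["gene_id"]) - known
            if orphan:
                raise ValueError(
                    f"expression rows reference unknown gene(s): {sorted(orphan)[:3]}"
                )
        out["expression"] = expression
    return out
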