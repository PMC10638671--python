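"""End-to-end pipeline: simulate -> preprocess -> diff -> classify ->
associate -> report.

Each stage communicates with the next only through its declared TSV
outputs in the run directory, so any stage can be re-run in isolation.
All randomness flows from one root seed through named substreams.  A
manifest records the configuration hash, the seed and per-stage row
counts; on failure an error manifest lists the stages that completed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    ALLELE_TOTAL,
    DISTAL_BP,
    PROXIMAL_BP,
    CountMatrix,
    GeneModel,
    PeakInterval,
)
from . import io as cio
from . import association as assoc
from .differential import CONTRAST_PARENTS
from .modes import ClassifyConfig, classify_all, count_mode_switches, mode_tallies
from .preprocess import cpm_filter, pca, size_factors, transform
from .simulate import (
    SimulationDesign,
    make_annotation,
    make_truth,
    simulate_counts,
    simulate_expression_table,
    truth_to_frame,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "preprocess", "diff", "classify", "associate", "report"]


@dataclass
class SimulationSpec:
    """Declarative description of a synthetic dataset."""

    n_peaks: int = 1200
    n_genes: int = 300
    chrom_length: int = 3_000_000
    mode_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "conserved": 1 / 6,
            "cis": 1 / 6,
            "trans": 1 / 6,
            "cis_plus_trans": 1 / 6,
            "cis_x_trans": 1 / 6,
            "compensatory": 1 / 6,
        }
    )
    effect_size: float | list = 1.5
    baseline_mean: float = 300.0
    dispersion: float = 0.05
    trans_dominance: float = 0.5
    replicates: int = 3
    coupling_odds: float = 1.0
    grn_fraction: float = 0.1
    tf_fraction: float = 0.3


@dataclass
class PipelineConfig:
    """Everything a run needs; CLI flags override file values."""

    outdir: str = "run"
    seed: int = 0
    alpha: float = 0.05
    use_adjusted_p: bool = True
    pseudocount: float = 0.5
    min_cpm: float = 3.0
    min_fraction: float = 1 / 3
    window_bp: int = DISTAL_BP
    proximal_bp: int = PROXIMAL_BP
    require_parental_sig: bool = True
    simulation: SimulationSpec | None = field(default_factory=SimulationSpec)
    # paths used when simulation is None
    counts_path: str | None = None
    samples_path: str | None = None
    peaks_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.window_bp >= self.proximal_bp > 0:
            raise ValueError("need window_bp >= proximal_bp > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.simulation is None:
            missing = [
                name
                for name, val in (
                    ("counts", self.counts_path),
                    ("samples", self.samples_path),
                    ("peaks", self.peaks_path),
                )
                if val is None
            ]
            if missing:
                raise ValueError(
                    f"no simulation spec and no input path(s) for: {missing}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", "default")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if sim is None:
            return cls(simulation=None, **raw)
        if sim == "default":
            return cls(**raw)
        return cls(simulation=SimulationSpec(**sim), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _substream_seeds(seed: int) -> dict[str, int]:
    """Named substreams derived from the root seed (each < 2**31)."""
    ss = np.random.SeedSequence(seed)
    names = ["truth", "counts", "annotation", "expression"]
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    spec = config.simulation
    seeds = _substream_seeds(config.seed)
    effect = spec.effect_size
    if isinstance(effect, list):
        effect = tuple(effect)
    truth = make_truth(
        spec.n_peaks,
        dict(spec.mode_proportions),
        effect_size_law=effect,
        seed=seeds["truth"],
        baseline_mean=spec.baseline_mean,
        dispersion=spec.dispersion,
        trans_dominance=spec.trans_dominance,
    )
    design = SimulationDesign(
        replicates_per_cross=spec.replicates,
        seed=seeds["counts"],
        coupling_odds=spec.coupling_odds,
    )
    cm, descriptors = simulate_counts(truth, design)
    genes, peaks, distances = make_annotation(
        spec.n_genes,
        spec.chrom_length,
        truth,
        grn_fraction=spec.grn_fraction,
        tf_fraction=spec.tf_fraction,
        seed=seeds["annotation"],
    )
    expression = simulate_expression_table(
        genes,
        truth,
        distances,
        spec.coupling_odds,
        seed=seeds["expression"],
        stages=design.stages,
    )
    cio.write_counts(cm, outdir / "counts.tsv")
    cio.write_samples(descriptors, outdir / "samples.tsv")
    cio.write_peaks_bed(peaks, outdir / "peaks.bed")
    cio.write_genes(genes, outdir / "genes.tsv")
    cio.write_expression(expression, outdir / "expression.tsv")
    cio.write_truth(truth_to_frame(truth), outdir / "truth.tsv")
    return {"peaks": len(truth), "samples": len(descriptors), "genes": len(genes)}


def stage_preprocess(config: PipelineConfig, outdir: Path) -> dict:
    if config.simulation is not None:
        paths = {
            "counts": outdir / "counts.tsv",
            "samples": outdir / "samples.tsv",
            "peaks": outdir / "peaks.bed",
        }
    else:
        paths = {
            "counts": Path(config.counts_path),
            "samples": Path(config.samples_path),
            "peaks": Path(config.peaks_path),
        }
    data = cio.read_inputs(paths["counts"], paths["samples"], paths["peaks"])
    cm, descriptors = data["counts"], data["descriptors"]
    cm = cpm_filter(cm, descriptors, config.min_cpm, config.min_fraction)
    cm = size_factors(cm, descriptors)
    cio.write_counts(cm, outdir / "filtered_counts.tsv")
    cm.size_factors.rename("size_factor").to_frame().rename_axis("sample_id").to_csv(
        outdir / "size_factors.tsv", sep="\t"
    )
    transformed = transform(cm)
    coords, fractions = pca(transformed)
    coords.rename_axis("sample_id").to_csv(
        outdir / "pca_coordinates.tsv", sep="\t", float_format="%.6g"
    )
    pd.DataFrame(
        {"component": [f"PC{i+1}" for i in range(len(fractions))],
         "variance_fraction": fractions}
    ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g")
    return {"peaks_retained": cm.shape[0], "samples": cm.shape[1]}


def _load_filtered(config: PipelineConfig, outdir: Path):
    cm = cio.read_counts(outdir / "filtered_counts.tsv")
    sf = pd.read_csv(outdir / "size_factors.tsv", sep="\t", index_col="sample_id")[
        "size_factor"
    ]
    cm = CountMatrix(cm.counts, sf)
    samples_path = (
        outdir / "samples.tsv" if config.simulation is not None else Path(config.samples_path)
    )
    descriptors = cio.read_samples(samples_path)
    descriptors = [d for d in descriptors if d.sample_id in set(cm.sample_ids)]
    return cm, descriptors


def stage_diff_and_classify(config: PipelineConfig, outdir: Path) -> dict:
    cm, descriptors = _load_filtered(config, outdir)
    cc = ClassifyConfig(
        alpha=config.alpha,
        use_adjusted_p=config.use_adjusted_p,
        pseudocount=config.pseudocount,
        require_parental_sig=config.require_parental_sig,
    )
    calls = classify_all(cm, descriptors, cc)
    calls.to_csv(outdir / "mode_calls.tsv", sep="\t", index=False, float_format="%.6g")

    long = []
    for contrast in ("P", "H", "M", "F", "T"):
        long.append(
            calls[["peak_id", "stage", f"padj_{contrast}"]]
            .rename(columns={f"padj_{contrast}": "padj"})
            .assign(contrast=contrast)
        )
    pd.concat(long, ignore_index=True).to_csv(
        outdir / "differential.tsv", sep="\t", index=False, float_format="%.6g"
    )
    tallies = mode_tallies(calls)
    tallies.to_csv(outdir / "mode_tallies.tsv", sep="\t", index=False, float_format="%.6g")

    stages = list(dict.fromkeys(calls["stage"]))
    if len(stages) >= 2:
        for which in ("inheritance", "regulatory"):
            switches, matrix = count_mode_switches(calls, which)
            matrix.rename_axis("from_mode").to_csv(
                outdir / f"switch_matrix_{which}.tsv", sep="\t"
            )
    return {"mode_calls": len(calls)}


def stage_associate(config: PipelineConfig, outdir: Path) -> dict:
    calls = pd.read_csv(outdir / "mode_calls.tsv", sep="\t")
    peaks_path = (
        outdir / "peaks.bed" if config.simulation is not None else Path(config.peaks_path)
    )
    genes_path = (
        outdir / "genes.tsv" if config.simulation is not None else Path(config.genes_path)
    )
    expr_path = (
        outdir / "expression.tsv"
        if config.simulation is not None
        else Path(config.expression_path)
    )
    if genes_path is None or expr_path is None:
        raise ValueError("association requested but genes/expression inputs missing")
    peaks = [p for p in cio.read_peaks_bed(peaks_path) if p.peak_id in set(calls["peak_id"])]
    genes = cio.read_genes(genes_path)
    expression = cio.read_expression(expr_path)

    links = assoc.nearest_gene(peaks, genes)
    links.to_csv(outdir / "links.tsv", sep="\t", index=False, float_format="%.6g")

    rows = []
    for stage, sub in calls.groupby("stage", sort=False):
        sub = sub.set_index("peak_id")
        da = (sub["padj_P"] <= config.alpha).to_dict()
        expr_stage = expression[expression["stage"] == stage].set_index("gene_id")
        de = expr_stage["de_status"].astype(bool).to_dict()
        de = {g.gene_id: de.get(g.gene_id, False) for g in genes}
        tests = {}
        try:
            tests["peaks_focused"] = assoc.peaks_focused_test(links, da, de)
        except ValueError as exc:
            logger.warning("peaks_focused failed at %s: %s", stage, exc)
        try:
            tests["gene_focused"] = assoc.gene_focused_test(
                genes, peaks, da, de, config.window_bp
            )
        except ValueError as exc:
            logger.warning("gene_focused failed at %s: %s", stage, exc)
        try:
            modes = expr_stage["expr_mode"].to_dict()
            modes = {g.gene_id: modes.get(g.gene_id, "conserved") for g in genes}
            cis_res, trans_res = assoc.regmode_focused_test(
                genes, peaks, da, modes, de, config.window_bp
            )
            tests["regmode_cis"] = cis_res
            tests["regmode_trans"] = trans_res
        except ValueError as exc:
            logger.warning("regmode_focused failed at %s: %s", stage, exc)
        for name, res in tests.items():
            rows.append(
                {
                    "test": name,
                    "stage": stage,
                    "n11": res.table[0, 0],
                    "n10": res.table[0, 1],
                    "n01": res.table[1, 0],
                    "n00": res.table[1, 1],
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "residual_11": res.residuals[0, 0],
                    "residual_10": res.residuals[0, 1],
                    "residual_01": res.residuals[1, 0],
                    "residual_00": res.residuals[1, 1],
                }
            )
    pd.DataFrame(rows).to_csv(
        outdir / "association.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # landscape: proximal/distal enrichment and gene-class densities
    land_rows = []
    linked = links.dropna(subset=["gene_id"])
    for stage, sub in calls.groupby("stage", sort=False):
        sub = sub.set_index("peak_id")
        da = sub["padj_P"] <= config.alpha
        for category in ("proximal", "distal"):
            in_cat = (linked["category"] == category).to_numpy()
            ind = da.reindex(linked["peak_id"]).fillna(False).to_numpy()
            try:
                res = assoc.category_enrichment(in_cat, ind, name=f"{category}_da")
                land_rows.append(
                    {
                        "stage": stage,
                        "contrast": f"{category}_da_rate",
                        "odds_ratio": res.odds_ratio,
                        "p": res.p,
                    }
                )
            except ValueError as exc:
                logger.warning("%s enrichment failed at %s: %s", category, stage, exc)
    density_all = assoc.peak_density(genes, peaks, config.window_bp)
    dens = pd.DataFrame({"gene_id": density_all.index, "n_peaks": density_all.to_numpy()})
    gene_by_id = {g.gene_id: g for g in genes}
    dens["is_tf"] = [gene_by_id[g].is_tf for g in dens["gene_id"]]
    dens["is_grn"] = [gene_by_id[g].is_grn for g in dens["gene_id"]]
    dens.to_csv(outdir / "density.tsv", sep="\t", index=False)
    pd.DataFrame(land_rows).to_csv(
        outdir / "landscape.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {"association_tests": len(rows)}


def stage_report(config: PipelineConfig, outdir: Path) -> dict:
    """Aggregate stage TSVs into a machine-readable summary.

    Every number here is re-derivable from the stage outputs; no new
    computation beyond aggregation happens in the report.
    """
    report: dict[str, Any] = {}
    tallies = pd.read_csv(outdir / "mode_tallies.tsv", sep="\t")
    report["mode_tallies"] = {
        f"{r.stage}.{r.classification}.{r.mode}": {"count": int(r.count), "proportion": r.proportion}
        for r in tallies.itertuples(index=False)
    }
    assoc_path = outdir / "association.tsv"
    if assoc_path.exists():
        at = pd.read_csv(assoc_path, sep="\t")
        report["association"] = at.to_dict(orient="records")
    pca_path = outdir / "pca_variance.tsv"
    if pca_path.exists():
        pv = pd.read_csv(pca_path, sep="\t")
        report["pca_variance_fractions"] = pv["variance_fraction"].tolist()
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return {"report_keys": len(report)}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage_fns = [
        ("simulate", stage_simulate) if config.simulation is not None else None,
        ("preprocess", stage_preprocess),
        ("classify", stage_diff_and_classify),
        ("associate", stage_associate),
        ("report", stage_report),
    ]
    try:
        for item in stage_fns:
            if item is None:
                continue
            name, fn = item
            manifest["stages"][name] = fn(config, outdir)
    except Exception as exc:
        manifest["error"] = {"stage": name, "message": str(exc)}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
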