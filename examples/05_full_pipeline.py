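"""Run the full pipeline end to end on a synthetic dataset.

Equivalent to `cistrans-atac run --outdir run_demo --seed 42` with the
default simulation; prints the mode tallies and where each output lives.
"""

import json
from pathlib import Path

import pandas as pd

from cistrans_atac.pipeline import PipelineConfig, SimulationSpec, run

outdir = Path("run_demo")
config = PipelineConfig(
    outdir=str(outdir),
    seed=42,
    simulation=SimulationSpec(n_peaks=1200, n_genes=400, chrom_length=80_000_000),
)
manifest = run(config)

print("Stages completed:", list(manifest["stages"]))
tallies = pd.read_csv(outdir / "mode_tallies.tsv", sep="\t")
print("\nRegulatory-mode counts per stage:")
print(
    tallies[tallies["classification"] == "regulatory"]
    .pivot(index="mode", columns="stage", values="count")
)
report = json.loads((outdir / "report.json").read_text())
print("\nPC1 variance fraction:", round(report["pca_variance_fractions"][0], 4))
print(
    "\nAll stage outputs are TSV files under run_demo/; rerunning with the "
    "same seed reproduces them byte for byte."
)
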