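"""Classify inheritance and regulatory modes on a mixed simulation.

Simulates 600 peaks split across the six regulatory modes, runs the full
filter/normalize/test/classify chain, and tabulates calls against truth.
"""

import pandas as pd

import cistrans_atac as ct
from cistrans_atac.simulate import truth_to_frame

truth = ct.make_truth(
    600, {m: 1 / 6 for m in ct.REGULATORY_MODES},
    effect_size_law=1.5, seed=11, baseline_mean=300.0, dispersion=0.05,
)
cm, descriptors = ct.simulate_counts(truth, ct.SimulationDesign(seed=12))
cm = ct.size_factors(ct.cpm_filter(cm, descriptors), descriptors)
calls = ct.classify_all(cm, descriptors)

tf = truth_to_frame(truth).reset_index(drop=True)[["peak_id", "true_regulatory_mode"]]
merged = calls.merge(tf, on="peak_id")
blastula = merged[merged["stage"] == "blastula"]

print("Confusion (rows = truth, columns = call), blastula stage:")
print(pd.crosstab(blastula["true_regulatory_mode"], blastula["regulatory_mode"]))

merged["hit"] = merged["regulatory_mode"] == merged["true_regulatory_mode"]
print("\nPer-class recovery across all stages:")
print(merged.groupby("true_regulatory_mode")["hit"].mean().round(3))

print("\nInheritance-mode tallies per stage:")
tallies = ct.mode_tallies(calls)
print(
    tallies[tallies["classification"] == "inheritance"]
    .pivot(index="mode", columns="stage", values="count")
)
print(
    "\nDiagonal dominance in the confusion matrix means the five-test "
    "decision table recovers the generating mechanism for most peaks."
)
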