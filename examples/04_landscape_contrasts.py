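"""Landscape contrasts: proximal vs distal peaks and GRN-gene neighborhoods.

Simulates a peak landscape with threefold peak density near developmental
gene-regulatory-network (GRN) genes, then (i) compares nearby-peak count
distributions for GRN genes, transcription factors and all genes, and
(ii) tests proximal-vs-distal differential-accessibility enrichment.
"""

import numpy as np

import cistrans_atac as ct
from cistrans_atac.association import category_enrichment, group_compare, peak_density

truth = ct.make_truth(3000, {"conserved": 0.6, "cis": 0.2, "trans": 0.2}, seed=21)
genes, peaks, _ = ct.make_annotation(
    600, 100_000_000, truth, seed=22, grn_peak_weight=3.0
)

grn = [g for g in genes if g.is_grn]
tf = [g for g in genes if g.is_tf]
dens = {
    "all_genes": peak_density(genes, peaks),
    "tf_genes": peak_density(tf, peaks),
    "grn_genes": peak_density(grn, peaks),
}
print("Mean peaks within 25 kb of a gene:")
for name, d in dens.items():
    print(f"  {name}: {d.mean():.2f}")
ks = group_compare({"grn": dens["grn_genes"], "all": dens["all_genes"]}, "ks")
print(f"KS test GRN vs all genes: D = {ks['statistic']:.3f}, p = {ks['p']:.3g}")

# proximal/distal DA enrichment
links = ct.nearest_gene(peaks, genes).dropna(subset=["gene_id"])
da = {t.peak_id: t.true_regulatory_mode != "conserved" for t in truth}
ind = np.array([da[p] for p in links["peak_id"]])
for category in ("proximal", "distal"):
    in_cat = (links["category"] == category).to_numpy()
    res = category_enrichment(in_cat, ind, name=f"{category}_da")
    print(
        f"{category} peaks vs rest, DA rate: conditional OR = "
        f"{res.odds_ratio:.2f}, Fisher p = {res.p:.3g}"
    )

print(
    "\nA KS p-value << 0.05 with a larger GRN mean reflects the elevated "
    "peak density built into the landscape near GRN genes; the odds ratios "
    "measure whether a positional class is DA more often than the rest of "
    "the peak set."
)
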