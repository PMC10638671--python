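# cistrans-atac

Classify the genetic basis of evolutionary divergence in chromatin
accessibility from allele-specific ATAC-seq counts in interspecies F1
hybrids, and quantify how differential accessibility relates to
differential expression of nearby genes.

## The problem

When two closely related species differ in the accessibility of an open
chromatin region (OCR), the difference can be **cis**-based (a local
sequence change at the element) or **trans**-based (a change in the
diffusible nuclear environment — the abundance or activity of the
regulators that act on the element). An F1 hybrid separates the two:
both parental alleles sit in one shared nuclear environment, so

* a *cis* change reproduces the parental difference as allelic imbalance
  in the hybrid (one large peak, one small peak), while
* a *trans* change equalizes the hybrid's alleles even though the
  parents differ (two equal peaks).

Writing `L_P` for the log2 ratio of the two parental (same-species)
accessibilities and `L_H` for the log2 ratio of the hybrid's
maternal/paternal allele accessibilities, the cis component of the
divergence is `L_H` and the trans component is `L_P − L_H`. Five
negative-binomial Wald contrasts per peak and developmental stage —
parents (P), hybrid alleles (H), hybrid vs each parent (M, F), and the
ratio-divergence test T on `L_P − L_H` — feed two decision tables:

* **regulatory mode**: conserved, cis, trans, cis + trans, cis × trans,
  compensatory, or ambiguous;
* **inheritance mode**: conserved, additive, maternal/paternal dominant,
  over/underdominant, or ambiguous (position of the hybrid total signal
  relative to the parents).

The package also computes the evolutionary effect size
`ES = log2(mean_maternal_species / mean_paternal_species)`, mode
switching across stages, peak–gene association tests (chi-squared with
Pearson residuals, Fisher exact with conditional-MLE odds ratios), and
proximal/distal and gene-class landscape contrasts.

Because raw sequencing data are outside desk scale, a first-class
synthetic generator produces allele-specific count matrices with known
per-peak cis/trans ground truth, a gene annotation with controlled
peak-to-gene distances, and a matched gene-expression table whose DE
status is coupled to nearby peak truth with a configurable odds ratio.
Every analysis stage is validated against this ground truth.

## Worked example

```python
import cistrans_atac as ct

truth = ct.make_truth(600, {m: 1/6 for m in ct.REGULATORY_MODES},
                      effect_size_law=1.5, seed=11)
cm, descriptors = ct.simulate_counts(truth, ct.SimulationDesign(seed=12))
cm = ct.size_factors(ct.cpm_filter(cm, descriptors), descriptors)
calls = ct.classify_all(cm, descriptors)
```

Comparing `calls["regulatory_mode"]` with the generating truth
(`examples/02_classify_modes.py`) prints per-class recovery:

```
true_regulatory_mode
cis               0.957
cis_plus_trans    0.933
cis_x_trans       0.993
compensatory      0.887
conserved         0.857
trans             0.893
```

i.e. with 3 replicates per cross, a mean depth of 300 reads per peak and
log2 effects of 1.5, the five-test decision table recovers the
generating mechanism for ~86–99% of peaks depending on class. The other
examples cover the mean model (`01`), peak–gene association (`03`),
landscape contrasts (`04`) and the end-to-end pipeline (`05`).

The pipeline is also available as a thin CLI:

```bash
cistrans-atac run --outdir run_demo --seed 42
```

which writes counts, mode calls, association tables, a JSON report and a
manifest into the run directory, byte-reproducibly for a fixed seed.

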