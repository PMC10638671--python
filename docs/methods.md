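# Methods

## Generative model

Each peak carries a baseline accessibility `mu` (expected reads per peak
in the paternal-species cross), a cis effect `c` and a trans effect `t`
(both log2), a hybrid trans-dominance parameter `d ∈ [0, 1]`, and a
negative-binomial dispersion `alpha`. Expected normalized means are

| group                  | mean                    |
|------------------------|-------------------------|
| maternal-species total | `mu · 2^(c+t)`          |
| paternal-species total | `mu`                    |
| hybrid maternal allele | `(mu/2) · 2^(c+d·t)`    |
| hybrid paternal allele | `(mu/2) · 2^(d·t)`      |

Hybrid allele means use `mu/2` because the two alleles share one diploid
library; the hybrid total column is the exact sum of the two allele
draws, never an independent draw. Counts are NB with variance
`m + alpha·m²` (Poisson below dispersion 1e-12), scaled by per-library
depth multipliers.

The trans-dominance parameter `d` encodes how the hybrid nuclear
environment blends the parental trans factors: `d = 0.5` (default) is an
even blend, `d = 1.0` emulates full maternal dominance — under it a
truly trans peak's hybrid total equals the maternal-species mean, which
is what makes maternal-dominant inheritance calls modal for trans peaks.
The model does not distinguish maternal-effect trans regulation from
zygotic trans regulation; both flow through `d` and are labeled
identically.

Regulatory-mode classes constrain `(c, t)`: conserved `c = t = 0`; cis
`t = 0`; trans `c = 0`; cis_plus_trans same signs; compensatory
`c = −t` exactly; cis_x_trans opposite signs with `|t| = cx_trans_ratio · |c-law draw|`
(default ratio 2.0). The ratio parameter exists because opposite signs
with *equal* magnitudes is precisely the compensatory geometry; an
opposite-sign interaction is only a distinct, recoverable class when the
two magnitudes differ, and a ratio of 2 leaves all three of P, H and T
well powered. Class counts follow the requested proportions under
deterministic largest-remainder rounding.

### Annotation and expression coupling

Genes are placed uniformly on one synthetic chromosome (interior margin
wide enough for the largest distance stratum); each peak targets a gene
and is placed at a controlled center-to-TLS distance drawn from one of
three strata — proximal (≤ 500 bp), distal (501–25,000 bp), beyond
(25,001–100,000 bp) — with stratum assignment shuffled across peaks so
distance is independent of regulatory mode. `grn_peak_weight > 1` makes
peaks preferentially target GRN genes, producing elevated peak density
near them. The TLS (translation start site) is the gene anchor
throughout; distances are strand-agnostic.

The expression table emulates a companion transcriptome study. A gene is
*exposed* if ≥ 1 truly non-conserved peak lies within 25 kb of its TLS.
DE status is Bernoulli with base rate 0.2; exposure multiplies the odds
by `coupling_odds`. Among DE genes the expression mode is cis with base
probability 0.5, again odds-multiplied under exposure, so cis-based DE
concentrates near truly divergent chromatin. Monte-Carlo checks confirm
the realized odds ratio matches the requested one (target 3.0 recovered
within [2.5, 3.6] over seeds).

## Preprocessing

* **CPM filter**: a peak is kept when its counts-per-million reach
  `min_cpm` (default 3) in at least `ceil(min_fraction · n)` of the
  included samples (default 1/3). Split hybrid allele columns do not
  vote — they are half-depth views of the hybrid library — but are kept
  in the output. The filter is idempotent.
* **Size factors**: median-of-ratios against the per-peak geometric-mean
  reference, estimated from total columns only. Hybrid allele columns
  inherit their hybrid total column's factor so allelic ratios are never
  renormalized away. This estimator assumes most peaks are
  non-divergent; a composition in which every peak is divergent leaves
  the factors only weakly identified (see Limitations).
* **Transform**: `log2(count/size_factor + pseudocount)` (pseudocount 1
  for the transform, 0.5 inside test statistics). This is a parameter-free
  monotone stabilization adequate for sample-space PCA, not a fitted
  mean-variance curve.
* **PCA**: samples are observations; peaks are centered, not scaled;
  SVD with a deterministic sign convention. On data where the species
  effect dominates, PC1 separates the parental crosses with hybrid
  totals falling between them.
* **FRIP**: fraction of reads overlapping the merged peak set by ≥ 1 bp
  (half-open intervals). Hybrid samples binned by parent-of-origin are
  scored one FRIP per allele bin.

## Differential testing

Per-peak NB dispersion is a method-of-moments estimate pooled across
replicate groups: `alpha = max(floor, Σ(s²−m)(n−1) / Σ m²(n−1))`, with
groups being the parental totals and the hybrid allele columns (hybrid
totals are sums of two draws and are excluded from pooling). Groups are
pooled across stages by default since effects are per-stage-constant in
the model. Because the raw per-peak estimate has few degrees of freedom,
it is moderated toward the across-peak median (weight 0.5 on the
per-peak value) before entering the Wald variance; without moderation
the null rejection rate at nominal 0.05 was measured at 0.074, with it
0.063, and with the true dispersion 0.054.

The Wald contrast on size-factor-normalized means uses
`log2_ratio = log2((m₁+ψ)/(m₂+ψ))` with per-group log-scale variance
`(m + alpha·m²) / (n·(m+ψ)²)` evaluated at the group mean (the `ψ` in
the denominator keeps the variance finite at zero means; for `m ≫ ψ` it
is the plain delta-method form). Two-sided p-values come from the
standard normal. The ratio-divergence statistic is
`z = (L_P − L_H)/√(se_P² + se_H²)`; its log2_ratio column stores
`L_P − L_H`, the trans component. Benjamini–Hochberg adjustment is
applied within one family per (contrast, stage).

## Classification

Significance is `padj ≤ alpha` (default 0.05; raw p and alpha 0.1 are
config knobs). The decision tables are total and mutually exclusive over
all significance/sign patterns; exact mean ties and exact zero log-ratio
components fall to `ambiguous` rather than to an arbitrary side. The
`require_parental_sig` flag (default on) controls whether cis and trans
calls require the parental contrast to be significant, or the allelic
pattern (H, T) alone decides. Over/underdominance takes precedence over
additivity whenever the hybrid total mean falls strictly outside the
parental interval.

Effect size `ES = log2((mean_mat+ψ)/(mean_pat+ψ))` is computed for every
peak, including conserved ones, so that ranking and landscape contrasts
can use the full set. Top-k ranking is by descending |ES| with exact
ties broken by lexicographically smaller peak id.

## Association statistics

Chi-squared independence tests use the Yates continuity correction only
for 2×2 tables (matching the default of the common statistical
environments), while the reported Pearson residuals
`(O−E)/√E` are always uncorrected. Fisher's exact test reports the
conditional maximum-likelihood odds ratio and the two-sided p as the sum
of hypergeometric probabilities no larger than the observed table's.
Window queries are inclusive at the 25,000 bp bound; the
proximal/distal/beyond partition (≤ 500 / 501–25,000 / > 25,000 bp) is
exhaustive and exclusive. Group comparisons offer Welch's t, the
two-sample KS test, and one-way ANOVA with pairwise Scheffé decisions
(`T² > (k−1)·F_{α,k−1,N−k}`), which tolerates very unequal group sizes.

## Study conditions used by tests and the acceptance script

* Mode recovery: 1200 peaks, six equal classes, |c| = |t| = 1.5 log2,
  dispersion 0.05, baseline depth 300, 3 replicates per cross, 5 seeds.
* Global null: 2000 all-conserved peaks, one simulation.
* Effect-size ordering: |c| ~ U(1.5, 2.5) vs |t| ~ U(0.5, 1.5),
  400 peaks per seed, 20 seeds.
* Association: 5000 peaks, 2000 genes on a 400 Mb chromosome, 70%
  conserved truth, coupling odds 3 (power) and 1 (level), 20 seeds.
  The geometry was chosen so gene exposure (≥ 1 non-conserved peak
  within 25 kb) sits near 40%; with a much denser landscape exposure
  saturates and no association is detectable at any coupling strength.
  DA status in these checks is the generator's truth label, isolating
  the association machinery and the expression coupling from
  differential-test noise.
* End-to-end fixture: 1200 peaks, 400 genes, 80 Mb, default proportions.

These sizes are the package's validation conditions; all are set in one
place in the tests and the acceptance script and scale linearly if
larger runs are wanted.

## What the generator does and does not emulate

It reproduces the count-level structure the analysis consumes: three
crosses × three stages × replicates, split hybrid allele columns,
NB overdispersion, library-size variation, controlled peak-to-gene
distances, and truth-coupled expression. It does not model read-level
artifacts (mappability, allelic mapping bias, liftover loss), sequence
content or motifs, peak-calling uncertainty, correlated dispersion
structure across peaks, or stage-dependent effect sizes unless
explicitly switched on via `stage_effects`. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to upstream artifacts of real sequencing data.

## Known limitations

* The plug-in Wald with moderated MoM dispersion is slightly liberal in
  the extreme tails compared with a full NB GLM with shrunken
  dispersions; at the depths and replicate counts simulated here the
  difference is within a percent of nominal.
* Median-of-ratios normalization requires a mostly-null peak set; in
  adversarial compositions (every peak divergent, signs balanced) the
  parental contrast absorbs a small per-column factor error which
  propagates into the ratio-divergence test.
* Maternal-effect and zygotic trans regulation are not distinguishable
  from count data in this design; both are represented by `d`.
* A single synthetic chromosome is used; nothing in the geometry code
  depends on that, but multi-chromosome annotation is only exercised by
  unit tests, not the generator.
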