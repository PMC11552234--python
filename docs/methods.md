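# Methods

## Generative model

Each simulated experiment is one tissue × stage stratum with three sample
groups: parental species 1, parental species 2, and their F1 hybrids
(default replicate design 6 / 5 / 6). Per gene `g`:

1. Baseline expression `μ_g` is log-normal: `log2 μ_g ~ N(mean, sd)`
   (defaults 8 and 1.5). Only the shape matters — per-sample abundances
   are renormalized — but the spread determines how many genes sit near
   the 10-read filter boundary at a given depth.
2. A regulatory architecture is assigned in exact proportions
   (largest-remainder apportionment, then shuffled): `conserved`
   (c = t = 0), `cis_only` (c ≠ 0, t = 0), `trans_only` (c = 0, t ≠ 0),
   `cis_plus_trans` (c·t > 0) or `compensatory` (c = −t ≠ 0). Effect
   magnitudes are a fixed value or a uniform draw (default 2.0 log2
   units), with random signs; the default mixture
   (0.60 / 0.15 / 0.15 / 0.05 / 0.05) reflects a bulk-RNA-seq panel where
   most genes are conserved and combined or compensatory architectures
   are rarer than simple ones.
3. Expected expression: species1 `μ_g`; species2 `μ_g·2^(c+t)`; hybrid
   species1 allele `(μ_g/2)·2^(t·h)` and species2 allele
   `(μ_g/2)·2^(c+t·h)` with `h = hybrid_trans_share` (default 0.5, which
   puts total hybrid expression midway between the parents). The hybrid
   allelic log2 ratio is therefore exactly `c` and the species log2 ratio
   exactly `c + t`.
4. Per sample, expected expression is converted to relative abundance
   within that sample class, scaled to the library size (default 2×10⁶
   reads), and counts are drawn independently per gene/sample/allele from
   a negative binomial with `var = μ + αμ²` (default α = 0.1; α = 0
   degenerates to Poisson). The two hybrid allele columns are independent
   draws, matching per-allele counting of uniquely assignable reads.
5. Parental reads are assigned wholly to the own-species ortholog column
   (the clean composite-genome case); `mapping_bias` multiplies
   species-1-allele means before drawing to emulate imperfect assignment.

The same configuration and seed reproduce byte-identical tables.

The simulator works at gene-level counts: it does not model read-level
artifacts (positional bias, variant-aware assignment ambiguity beyond the
scalar `mapping_bias`), isoform switching, correlated biological
replicates, or gene-specific dispersions. Passing recovery tests
demonstrate that the statistical machinery is correct under a clean NB
model, not that real libraries satisfy that model.

## Analysis pipeline

Strata are analyzed independently and never pooled.

**Filter.** A gene is excluded if it has fewer than `min_reads` (default
10) reads in any sample of the stratum. The count compared to the
threshold is the *sum* over the gene's two ortholog columns
(`filter_mode="sum"`, the permissive reading); `filter_mode="each"`
requires each hybrid allele, and the parental own-species ortholog,
to reach the threshold individually.

**Normalization.** Each sample's counts are divided by a size factor;
hybrid size factors are estimated on the allele-summed counts *before*
segregating the two alleles, so both allele columns share one factor and
the allelic ratio is never distorted. Two estimators are provided:

* `median_of_ratios` (default): per sample, the median across genes of
  the ratio to the per-gene geometric mean. By default a second pass
  re-anchors the median to genes with no DGE evidence (BH-adjusted
  p ≥ α on the first pass; `size_factor_refine`). This matters: when a
  large fraction of genes diverge and their directions are not perfectly
  balanced, the overall median sits off-center within the non-divergent
  block of the ratio distribution and every fold change inherits the
  offset; anchoring to non-divergent genes removes it. Plain total-count
  scaling is far worse here — the divergent mass shifts the denominator
  of every gene (an offset of ~0.6 log2 units under a 50%-divergent
  panel with 4-fold effects) — which is why counts-per-million is not
  the default for estimation.
* `cpm`: total-count scaling to one million per sample (per hybrid
  allele pair). Used for presentation (per-gene expression reports are
  printed in CPM) and available for estimation via configuration.

Size factors are computed on the unfiltered stratum table by default
(`size_factors_from="unfiltered"`), so the gene filter cannot distort
apparent depth; the filtered-table alternative is one setting away.

**Testing.** Parental expression per sample is the gene's combined
ortholog count; hybrid allelic expression is the per-allele count. Values
are normalized, transformed as `log2(x + 1)` (pseudocount configurable;
with the 10-read filter and default depth, typical normalized values are
≫ 10, so the pseudocount's influence is bounded), and compared with
Welch's unequal-variance *t*-test implemented from the defining formulas
(Welch–Satterthwaite degrees of freedom; two-sided p from the
t-distribution). The reported log2 fold change is the difference of group
means of the transformed values — the same quantity the test tests.
Genes with zero variance in both groups get the limiting p-values (1 for
equal means, 0 otherwise) and a `degenerate` flag.

Direction convention: fold changes are `other − reference` with
`reference="species1"` by default, so positive DGE means higher in
species 2 and equals `c + t` under the generative model; the reference is
configurable when the opposite sign convention is wanted for reporting.

**Multiple testing.** Benjamini–Hochberg step-up adjustment, implemented
from the formula, applied per stratum and separately to the DGE and ASE
p-value families.

**Classification** (α = 0.05, configurable): cis if both contrasts are
significant with the same nonzero sign; trans if only DGE is significant;
conserved if neither; ambiguous otherwise (ASE-only significance, or both
significant with opposite signs — compensatory-like — or a fold change of
exactly 0, where direction agreement is undefined). Subtypes annotate the
ambiguous cells.

**Regression.** Closed-form OLS of ASE on DGE fold changes over all
tested genes (a subset can be supplied), with `r²`, adjusted
`r² = 1 − (1−r²)(n−1)/(n−2)` and the slope's t-test p-value.

**Recovery scoring.** Against simulation truth: a confusion matrix of
architecture × called category, sensitivity per architecture (expected
calls: conserved→conserved, cis_only→cis, trans_only→trans,
cis_plus_trans→cis) and precision per category. Compensatory genes are
reported but not scored — their species-level expression is conserved
while their alleles are imbalanced, so the cis/trans rule has no correct
cell for them; they surface as ambiguous (opposite-sign) or conserved
calls depending on power.

## Numerical and design notes

* The hybrid alleles within one animal are paired observations; following
  the unpaired Welch convention for both contrasts keeps DGE and ASE on
  the same footing. A paired alternative would gain power at equal
  dispersion but is not implemented.
* BH family boundaries (per stratum, per contrast) and the pseudocount
  are choices the classification rule is sensitive to only near the
  significance boundary; both are surfaced in `AnalysisSettings`.
* Filtering precedes normalization; raising the threshold can only
  shrink the kept gene set (monotone).
* Problem sizes used by the test suite and the acceptance script — up to
  10,000 genes × 17 samples for null calibration and 1,000 genes for
  recovery — run in seconds and give Monte-Carlo error well inside the
  asserted tolerances (e.g. a ±0.01 band on a 0.05 type-I rate at
  n ≈ 9,400 is ≈ 4.5 binomial standard errors).

## Known limitations

* A single dispersion for all genes; real data show mean-dependent,
  gene-specific dispersion.
* No moderated/shrunken variance estimation — small-replicate designs
  lean entirely on Welch's test, which is slightly conservative at these
  group sizes (observed null rejection ≈ 0.044 at nominal 0.05).
* The ortholog map is one-to-one; paralog collapse or missing orthologs
  must be resolved upstream.
* No batch structure, GC/length normalization, or per-SNP
  (binomial/beta-binomial) ASE testing.
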