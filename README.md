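# hybridase

Partitioning between-species gene-expression divergence into *cis*- and
*trans*-regulatory components from allele-specific expression (ASE) in F1
interspecific hybrids — with a fully ground-truthed synthetic count
generator so every stage of the analysis can be validated without any
sequencing data.

## The biology and the statistic

When two species differ in a gene's expression, the difference can arise
in *cis* (changes in regulatory sequence linked to the gene — promoters,
enhancers) or in *trans* (changes in diffusible regulators such as
transcription factors). An F1 hybrid separates the two: both alleles sit
in the same trans-acting environment, so

* a purely **trans** difference is equalized — the two alleles are
  expressed at balanced levels in the hybrid;
* a **cis** difference travels with the allele — the alleles continue to
  be expressed at unequal levels.

Writing `c` and `t` for the cis and trans contributions in log2 units, the
between-species fold change (DGE) measures `c + t` while the hybrid
allelic fold change (ASE) measures `c` alone. Per gene, both contrasts
are tested with Welch's *t*-test on log2-transformed, library-size-
normalized counts, adjusted with Benjamini–Hochberg FDR separately per
contrast and per tissue × stage stratum, and classified:

| padj_DGE < α | padj_ASE < α | fold-change signs | category  |
|--------------|--------------|-------------------|-----------|
| yes          | yes          | same, nonzero     | cis       |
| yes          | no           | —                 | trans     |
| no           | no           | —                 | conserved |
| otherwise    |              |                   | ambiguous |

An ordinary least-squares regression of ASE on DGE fold changes summarizes
the genome-wide balance: a slope near 1 (the identity line) means
divergence is dominated by cis effects, a slope near 0 by trans effects.

The simulator draws per-gene negative-binomial counts
(`var = μ + αμ²`) for two parental species (6 and 5 replicates by
default), plus 6 F1 hybrids whose two allele columns are drawn
independently, with known per-gene `(c, t)` so that recovery of effects
and classifications can be scored exactly.

## Worked example

```bash
python examples/recovery_from_truth.py
```

```
confusion matrix (truth architecture x called category):
category        cis  trans  conserved  ambiguous
architecture
conserved         1      7        491          1
cis_only        248      0          0          0
trans_only        2    245          0          2

per-architecture sensitivity:
conserved     0.982
cis_only      1.000
trans_only    0.984

cis-subset ASE-vs-DGE slope:   0.990 (identity line: allelic imbalance mirrors the species difference)
trans-subset ASE-vs-DGE slope: 0.001 (hybrid alleles balanced despite the species difference)
mean ASE bias over cis genes:  +0.0045 log2 units
mean DGE bias over all genes:  +0.0020 log2 units
```

Out of 1,000 simulated genes (250 cis-only with |c| = 2, 250 trans-only
with |t| = 2, 500 conserved), every cis gene and 98% of trans genes are
recovered, under 2% of conserved genes are miscalled, and the two
regression slopes recover the cis (≈1) and trans (≈0) expectations; the
fold-change estimators are unbiased to well under 0.05 log2 units.

`examples/simulate_and_classify.py` runs the default mixed-architecture
design end to end, and `examples/gene_report_demo.py` prints a per-gene
CPM summary (parental groups, hybrid totals, hybrid per-allele values) of
a cis-regulated gene, showing the hybrid total intermediate between the
parents while its alleles stay imbalanced.

The same pipeline is scriptable from a shell:

```bash
hybridase simulate -o sim --seed 5
hybridase run --counts sim/counts.tsv --metadata sim/metadata.tsv \
              --ortholog-map sim/ortholog_map.tsv -o out
hybridase report --results out/results.tsv --truth sim/truth.tsv -o report.json
```

All tables are strict TSV (`<sample>__<ortholog>` count columns); every
run writes a manifest with a config hash and file digests, and identical
inputs + seed reproduce byte-identical outputs.

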