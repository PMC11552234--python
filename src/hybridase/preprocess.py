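"""Gene filtering and library-size normalization, per tissue x stage stratum.

The filter drops any gene whose combined ortholog counts fall below a
minimum read threshold in any sample of the stratum (default 10 reads).
Normalization divides each sample's counts by a size factor; crucially,
hybrid size factors are estimated on the allele-summed counts *before*
segregating the two alleles, so both allele columns of a hybrid share one
size factor and the allelic ratio is never distorted by normalization.

Two size-factor estimators are available:

* ``median_of_ratios`` (default): DESeq-style — per sample, the median
  across genes of the ratio to the per-gene geometric mean.  Robust to a
  minority of strongly divergent genes, so fold-change estimates stay
  anchored to the conserved majority.
* ``cpm``: total-count scaling so every sample (or hybrid allele pair)
  sums to one million.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io_tables import SchemaError

__all__ = [
    "filter_min_reads",
    "estimate_size_factors",
    "normalize",
    "gene_totals",
    "NormalizedMatrix",
]


def _stratum_samples(meta: pd.DataFrame, stratum) -> pd.DataFrame:
    if stratum is None:
        return meta
    tissue, stage = stratum
    sub = meta[(meta["tissue"] == tissue) & (meta["stage"] == stage)]
    if len(sub) == 0:
        raise SchemaError(f"empty stratum: tissue={tissue!r}, stage={stage!r}")
    return sub


def gene_totals(counts: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Per-gene per-sample totals summed over the two ortholog columns."""
    if samples is not None:
        counts = counts.loc[:, (list(samples), slice(None))]
    return counts.T.groupby(level="sample", sort=False).sum().T


def filter_min_reads(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    stratum=None,
    threshold: int = 10,
    mode: str = "sum",
) -> tuple[pd.DataFrame, list[str]]:
    """Exclude genes with fewer than ``threshold`` reads in any sample.

    ``mode='sum'`` (default) requires the *sum* of a gene's two ortholog
    columns to reach the threshold in every sample of the stratum.
    ``mode='each'`` is the strict reading: hybrid samples need each allele
    individually above threshold; parental samples need the own-species
    ortholog above threshold (their other column is structurally zero).

    Returns the filtered table (columns restricted to the stratum) and the
    sorted list of dropped gene ids.
    """
    if mode not in ("sum", "each"):
        raise ValueError(f"mode must be 'sum' or 'each', got {mode!r}")
    sub = _stratum_samples(meta, stratum)
    samples = list(sub["sample_id"])
    table = counts.loc[:, (samples, slice(None))]
    totals = gene_totals(table)
    if mode == "sum":
        keep = (totals >= threshold).all(axis=1)
    else:
        keep = pd.Series(True, index=table.index)
        for _, row in sub.iterrows():
            sid, group = row["sample_id"], row["group"]
            if group == "hybrid":
                keep &= (table[(sid, "species1")] >= threshold) & (
                    table[(sid, "species2")] >= threshold
                )
            else:
                keep &= table[(sid, group)] >= threshold
    dropped = sorted(table.index[~keep])
    return table.loc[keep], dropped


@dataclass
class NormalizedMatrix:
    """Normalized per-gene, per-sample (and per-allele) expression values.

    ``values`` has the same (sample, ortholog) column layout as the count
    table; ``size_factors`` records the per-sample divisor (one shared
    factor for both allele columns of a hybrid); ``method`` names the
    estimator.  With ``method='cpm'`` a parental sample's values sum to
    1e6 and a hybrid's two allele columns jointly sum to 1e6.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    meta: pd.DataFrame
    method: str

    def sample_values(self, sample_id: str) -> pd.DataFrame:
        return self.values[sample_id]

    def total_expression(self) -> pd.DataFrame:
        """Per-gene per-sample normalized totals (alleles summed)."""
        return self.values.T.groupby(level="sample", sort=False).sum().T


def estimate_size_factors(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    method: str = "median_of_ratios",
    control_genes=None,
) -> pd.Series:
    """Per-sample size factors from allele-summed gene totals.

    Hybrid alleles are summed before estimation, so each hybrid sample gets
    a single factor applied to both of its allele columns.

    ``control_genes`` restricts the median-of-ratios to a gene subset.
    When many genes diverge with a net directional imbalance, the overall
    median sits off-center within the non-divergent block of the ratio
    distribution and every fold change inherits that offset; anchoring the
    median to genes with no evidence of divergence removes it.
    """
    sub = meta[meta["sample_id"].isin(counts.columns.get_level_values(0))]
    samples = list(sub["sample_id"])
    totals = gene_totals(counts, samples)
    col_sums = totals.sum(axis=0)
    if (col_sums == 0).any():
        zero = col_sums.index[col_sums == 0][0]
        raise SchemaError(f"sample {zero!r} has zero library size")
    if method == "cpm":
        sf = col_sums / 1e6
    elif method == "median_of_ratios":
        if control_genes is not None:
            control = totals.index.intersection(control_genes)
            if len(control) >= 10:  # too few anchors: keep the full median
                totals = totals.loc[control]
        log_totals = np.log(totals.where(totals > 0))
        log_geomean = log_totals.mean(axis=1, skipna=False)
        usable = np.isfinite(log_geomean)
        if usable.sum() == 0:
            raise SchemaError(
                "median-of-ratios size factors need at least one gene with "
                "nonzero counts in every sample; none found"
            )
        ratios = np.log(totals.loc[usable]).sub(log_geomean[usable], axis=0)
        sf = np.exp(ratios.median(axis=0))
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    sf.name = "size_factor"
    sf.index.name = "sample"
    return sf


def normalize(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    method: str = "median_of_ratios",
    size_factor_source: Optional[pd.DataFrame] = None,
    control_genes=None,
) -> NormalizedMatrix:
    """Library-size normalize a (filtered) count table.

    ``size_factor_source`` lets size factors be estimated on a different
    (typically the unfiltered) table, so the gene filter cannot distort
    apparent sequencing depth; the factors are then applied to ``counts``.
    ``control_genes`` anchors median-of-ratios factors to a subset (see
    :func:`estimate_size_factors`).
    """
    source = counts if size_factor_source is None else size_factor_source
    sf = estimate_size_factors(source, meta, method=method, control_genes=control_genes)
    samples = counts.columns.get_level_values(0)
    missing = set(samples) - set(sf.index)
    if missing:
        raise SchemaError(
            f"size-factor source lacks sample(s) {sorted(missing)[:5]}"
        )
    divisors = sf.loc[samples].to_numpy()
    values = counts.astype(float).div(divisors, axis=1)
    sub = meta[meta["sample_id"].isin(set(samples))]
    return NormalizedMatrix(
        values=values, size_factors=sf.loc[sub["sample_id"]].copy(),
        meta=sub.reset_index(drop=True), method=method,
    )
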