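"""End-to-end orchestration: filter -> normalize -> test -> adjust ->
classify -> regress, independently per tissue x stage stratum, plus a run
manifest that proves determinism.

BH adjustment is applied within each stratum, separately for the DGE and
the ASE p-value families; strata are never pooled.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import AnalysisSettings
from .cistrans import ase_dge_regression, ase_test, classify, dge_test
from .io_tables import SchemaError, check_samples_match
from .preprocess import filter_min_reads, normalize
from .stats import bh_adjust

__all__ = ["StratumResult", "PipelineResult", "analyze_stratum", "run_pipeline"]


@dataclass
class StratumResult:
    """Results of one tissue x stage stratum."""

    stratum: str
    results: pd.DataFrame
    regression: "object"
    dropped_genes: list
    n_input: int
    untestable_genes: list = field(default_factory=list)

    def category_counts(self) -> dict:
        return self.results["category"].value_counts().to_dict()


@dataclass
class PipelineResult:
    strata: list
    settings: AnalysisSettings

    @property
    def results(self) -> pd.DataFrame:
        return pd.concat([s.results for s in self.strata], ignore_index=True)

    def manifest(self, seed: Optional[int] = None, inputs: Optional[dict] = None) -> dict:
        stages = {}
        for s in self.strata:
            stages[s.stratum] = {
                "n_input": s.n_input,
                "n_filtered_out": len(s.dropped_genes),
                "n_tested": int(len(s.results)),
                "categories": s.category_counts(),
            }
        return {
            "software": "hybridase",
            "version": __version__,
            "config_hash": self.settings.config_hash(),
            "settings": self.settings.to_dict(),
            "seed": seed,
            "inputs": inputs or {},
            "strata": stages,
        }


def analyze_stratum(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    stratum: tuple,
    settings: AnalysisSettings = AnalysisSettings(),
) -> StratumResult:
    """Run the full per-stratum analysis.

    Order of operations: restrict to the stratum's samples; drop genes
    under the minimum-read threshold; estimate size factors (by default on
    the *unfiltered* stratum table, so filtering cannot distort apparent
    depth) and normalize; Welch-test DGE on parental totals and ASE on
    hybrid alleles; BH-adjust the two p-value families separately;
    classify; regress ASE on DGE over all tested genes.
    """
    tissue, stage = stratum
    stratum_label = f"{tissue}:{stage}"
    sub = meta[(meta["tissue"] == tissue) & (meta["stage"] == stage)]
    if len(sub) == 0:
        raise SchemaError(f"empty stratum: tissue={tissue!r}, stage={stage!r}")
    for group in ("species1", "species2", "hybrid"):
        n = (sub["group"] == group).sum()
        if n < 2:
            raise SchemaError(
                f"stratum {stratum_label}: group {group!r} has {n} samples; "
                "need >= 2"
            )
    stratum_counts = counts.loc[:, (list(sub["sample_id"]), slice(None))]
    n_input = len(stratum_counts)
    filtered, dropped = filter_min_reads(
        stratum_counts, sub, None, threshold=settings.min_reads,
        mode=settings.filter_mode,
    )
    source = stratum_counts if settings.size_factors_from == "unfiltered" else None
    norm = normalize(
        filtered, sub, method=settings.norm_method, size_factor_source=source
    )
    dge = dge_test(norm, settings.pseudocount, settings.reference)
    if settings.size_factor_refine and settings.norm_method == "median_of_ratios":
        # Second pass: anchor size factors to genes without DGE evidence so
        # a directional imbalance of divergent genes cannot offset every
        # fold change through the median.
        padj1 = bh_adjust(dge["p_dge"].to_numpy())
        control = dge.index[padj1 >= settings.alpha]
        norm = normalize(
            filtered, sub, method=settings.norm_method,
            size_factor_source=source, control_genes=control,
        )
        dge = dge_test(norm, settings.pseudocount, settings.reference)
    ase = ase_test(norm, settings.pseudocount, settings.reference)

    # Degenerate genes (zero variance in both groups) keep their limiting
    # p-values and stay in the BH family; genes become untestable only via
    # group sizes < 2, which is rejected above, so no exclusions here.
    dge["padj_dge"] = bh_adjust(dge["p_dge"].to_numpy())
    ase["padj_ase"] = bh_adjust(ase["p_ase"].to_numpy())

    calls = classify(dge, ase, alpha=settings.alpha)
    results = pd.DataFrame(
        {
            "gene_id": dge.index,
            "stratum": stratum_label,
            "log2fc_dge": dge["log2fc_dge"].to_numpy(),
            "p_dge": dge["p_dge"].to_numpy(),
            "padj_dge": dge["padj_dge"].to_numpy(),
            "log2fc_ase": ase["log2fc_ase"].to_numpy(),
            "p_ase": ase["p_ase"].to_numpy(),
            "padj_ase": ase["padj_ase"].to_numpy(),
            "category": calls["category"].to_numpy(),
            "subtype": calls["subtype"].to_numpy(),
        }
    )
    try:
        regression = ase_dge_regression(results)
    except ValueError:
        regression = None
    return StratumResult(
        stratum=stratum_label,
        results=results,
        regression=regression,
        dropped_genes=dropped,
        n_input=n_input,
    )


def run_pipeline(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    settings: AnalysisSettings = AnalysisSettings(),
    strata: Optional[list] = None,
) -> PipelineResult:
    """Analyze every tissue x stage stratum present in the metadata (or the
    given subset), independently."""
    check_samples_match(counts, meta)
    if strata is None:
        strata = list(
            meta[["tissue", "stage"]].drop_duplicates().itertuples(index=False)
        )
        strata = [(t, s) for t, s in strata]
    out = [analyze_stratum(counts, meta, st, settings) for st in strata]
    return PipelineResult(strata=out, settings=settings)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
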