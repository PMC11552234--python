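"""Per-gene DGE and ASE testing, cis/trans classification, the ASE-vs-DGE
regression, recovery scoring against simulation truth, and per-gene reports.

The logic of the design: a between-species expression difference that arose
in *cis* travels with the allele, so it persists as allelic imbalance in an
F1 hybrid; one that arose in *trans* is equalized in the hybrid because
both alleles share the same trans-acting environment.  DGE therefore
measures ``c + t`` and hybrid ASE measures ``c`` alone; genes significant
for both, in the same direction, are called cis-regulated, and genes
significant only for DGE are called trans-regulated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .config import ARCHITECTURES
from .io_tables import SchemaError
from .preprocess import NormalizedMatrix
from .stats import bh_adjust, log2_transform, welch_t_test_matrix

__all__ = [
    "dge_test",
    "ase_test",
    "classify",
    "ase_dge_regression",
    "recovery_metrics",
    "gene_report",
    "RegressionSummary",
    "RecoveryReport",
    "GeneReport",
    "CATEGORIES",
]

CATEGORIES = ("cis", "trans", "conserved", "ambiguous")

#: Category a truth architecture is expected to land in (compensatory genes
#: are reported but not scored: their DGE is null while ASE is real, so the
#: cis/trans rule has no correct cell for them).
EXPECTED_CALL = {
    "conserved": "conserved",
    "cis_only": "cis",
    "trans_only": "trans",
    "cis_plus_trans": "cis",
}


def _group_log2(
    norm: NormalizedMatrix, group: str, pseudocount: float
) -> pd.DataFrame:
    samples = norm.meta.loc[norm.meta["group"] == group, "sample_id"]
    totals = norm.total_expression()[list(samples)]
    return log2_transform(totals, pseudocount)


def dge_test(
    norm: NormalizedMatrix,
    pseudocount: float = 1.0,
    reference: str = "species1",
) -> pd.DataFrame:
    """Per-gene differential expression between the two parental species.

    Each parental sample's expression is the gene's combined ortholog
    count, normalized and log2(x + pseudocount)-transformed; the test is
    Welch's t.  With the default ``reference='species1'``, positive
    ``log2fc_dge`` means higher expression in species2, matching the
    simulator's ``expected_dge = c + t`` convention.
    """
    for group in ("species1", "species2"):
        n = (norm.meta["group"] == group).sum()
        if n < 2:
            raise SchemaError(
                f"dge_test needs >= 2 replicates of {group}, got {n}"
            )
    other = "species2" if reference == "species1" else "species1"
    X = _group_log2(norm, other, pseudocount)
    Y = _group_log2(norm, reference, pseudocount)
    est, t, df, p, degen = welch_t_test_matrix(X.to_numpy(), Y.to_numpy())
    return pd.DataFrame(
        {
            "log2fc_dge": est,
            "t_dge": t,
            "df_dge": df,
            "p_dge": p,
            "degenerate_dge": degen,
        },
        index=X.index,
    )


def ase_test(
    norm: NormalizedMatrix,
    pseudocount: float = 1.0,
    reference: str = "species1",
) -> pd.DataFrame:
    """Per-gene allele-specific expression within F1 hybrids.

    The two allele columns of each hybrid are normalized by that sample's
    single shared size factor, so the allelic contrast is untouched by
    depth differences between hybrids.  With ``reference='species1'``,
    positive ``log2fc_ase`` means the species2 allele is higher, matching
    the simulator's ``expected_ase = c`` convention.
    """
    hybrids = norm.meta.loc[norm.meta["group"] == "hybrid", "sample_id"]
    if len(hybrids) < 2:
        raise SchemaError(
            f"ase_test needs >= 2 hybrid replicates, got {len(hybrids)}"
        )
    other = "species2" if reference == "species1" else "species1"
    vals = norm.values
    X = log2_transform(
        vals.loc[:, (list(hybrids), other)].droplevel("ortholog", axis=1),
        pseudocount,
    )
    Y = log2_transform(
        vals.loc[:, (list(hybrids), reference)].droplevel("ortholog", axis=1),
        pseudocount,
    )
    est, t, df, p, degen = welch_t_test_matrix(X.to_numpy(), Y.to_numpy())
    return pd.DataFrame(
        {
            "log2fc_ase": est,
            "t_ase": t,
            "df_ase": df,
            "p_ase": p,
            "degenerate_ase": degen,
        },
        index=vals.index,
    )


def classify(
    dge: pd.DataFrame, ase: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the cis/trans rule to adjusted p-values.

    cis        — both DGE and ASE significant (padj < alpha) with the same
                 nonzero fold-change sign;
    trans      — DGE significant, ASE not;
    ambiguous  — ASE significant without DGE (subtype ``ase_only``), or
                 both significant with opposite or undefined signs
                 (subtype ``opposite_sign`` / ``sign_tie``);
    conserved  — neither significant.

    ``dge`` needs columns ``log2fc_dge``/``padj_dge``; ``ase`` needs
    ``log2fc_ase``/``padj_ase``; indexes must agree.
    """
    for frame, cols in ((dge, ("log2fc_dge", "padj_dge")),
                        (ase, ("log2fc_ase", "padj_ase"))):
        for col in cols:
            if col not in frame.columns:
                raise SchemaError(f"classify: missing column {col!r}")
    if not dge.index.equals(ase.index):
        raise SchemaError("classify: DGE and ASE gene indexes differ")
    padj_dge = dge["padj_dge"].to_numpy()
    padj_ase = ase["padj_ase"].to_numpy()
    if np.isnan(padj_dge).any() or np.isnan(padj_ase).any():
        raise SchemaError("classify: missing padj values")
    sig_dge = padj_dge < alpha
    sig_ase = padj_ase < alpha
    sign_dge = np.sign(dge["log2fc_dge"].to_numpy())
    sign_ase = np.sign(ase["log2fc_ase"].to_numpy())
    same_sign = (sign_dge == sign_ase) & (sign_dge != 0)

    category = np.full(len(dge), "conserved", dtype=object)
    subtype = np.full(len(dge), "", dtype=object)
    category[sig_dge & ~sig_ase] = "trans"
    category[sig_dge & sig_ase & same_sign] = "cis"
    both_not_same = sig_dge & sig_ase & ~same_sign
    category[both_not_same] = "ambiguous"
    subtype[both_not_same] = np.where(
        (sign_dge[both_not_same] == 0) | (sign_ase[both_not_same] == 0),
        "sign_tie",
        "opposite_sign",
    )
    ase_only = ~sig_dge & sig_ase
    category[ase_only] = "ambiguous"
    subtype[ase_only] = "ase_only"
    return pd.DataFrame({"category": category, "subtype": subtype}, index=dge.index)


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary of hybrid ASE (y) on species DGE (x) log2 fold changes.

    A slope near 1 (the identity line) means allelic imbalance in hybrids
    fully mirrors the species difference — divergence in cis; a slope near
    0 means hybrid alleles are balanced regardless of the species
    difference — divergence in trans.
    """

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "p_value": self.p_value,
            "n": self.n,
        }


def ase_dge_regression(
    results: pd.DataFrame, gene_subset: Optional[Iterable[str]] = None
) -> RegressionSummary:
    """Closed-form OLS of ``log2fc_ase`` on ``log2fc_dge``.

    ``gene_subset`` restricts the fit (default: all tested genes).  The
    slope p-value comes from the t distribution with n - 2 df; adjusted
    R^2 is ``1 - (1 - r2)(n - 1)/(n - 2)``.
    """
    df = results
    if gene_subset is not None:
        subset = list(gene_subset)
        df = df[df["gene_id"].isin(subset)] if "gene_id" in df.columns else df.loc[subset]
    x = df["log2fc_dge"].to_numpy(dtype=float)
    y = df["log2fc_ase"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"regression needs >= 3 genes, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("zero variance in log2fc_dge; slope undefined")
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r2 = 0.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rss = syy - slope * sxy
    if rss <= 0.0:  # perfect fit up to rounding
        p_value = 0.0
    else:
        se = math.sqrt(rss / (n - 2) / sxx)
        t_stat = slope / se
        p_value = float(2.0 * t_dist.sf(abs(t_stat), n - 2))
    return RegressionSummary(
        slope=float(slope),
        intercept=intercept,
        r2=float(r2),
        adj_r2=float(adj_r2),
        p_value=p_value,
        n=int(n),
    )


@dataclass
class RecoveryReport:
    """Confusion matrix of truth architecture x called category, with
    per-architecture sensitivity and per-category precision.

    Compensatory genes appear in the matrix but are excluded from the
    rates: the cis/trans rule has no correct cell for cancelling effects.
    """

    confusion: pd.DataFrame
    sensitivity: pd.Series
    precision: pd.Series

    def to_dict(self) -> dict:
        return {
            "confusion": {
                arch: self.confusion.loc[arch].to_dict()
                for arch in self.confusion.index
            },
            "sensitivity": self.sensitivity.to_dict(),
            "precision": self.precision.to_dict(),
        }


def recovery_metrics(truth: pd.DataFrame, results: pd.DataFrame) -> RecoveryReport:
    """Score classification calls against simulation ground truth.

    ``truth`` carries ``gene_id``/``architecture``; ``results`` carries
    ``gene_id``/``category``.  Genes dropped by the read filter before
    testing are tolerated (scored only over tested genes), but any tested
    gene missing from the truth table is an error.
    """
    t = truth.set_index("gene_id")
    r = results.set_index("gene_id")
    unknown = r.index.difference(t.index)
    if len(unknown) > 0:
        raise SchemaError(
            f"results contain gene ids absent from truth: {list(unknown[:5])}"
        )
    merged = r[["category"]].join(t[["architecture"]])
    confusion = (
        pd.crosstab(merged["architecture"], merged["category"])
        .reindex(index=list(ARCHITECTURES), columns=list(CATEGORIES), fill_value=0)
    )
    confusion.index.name = "architecture"
    confusion.columns.name = "category"

    sens = {}
    for arch, expected in EXPECTED_CALL.items():
        total = confusion.loc[arch].sum()
        sens[arch] = (
            float(confusion.loc[arch, expected] / total) if total else np.nan
        )
    prec = {}
    for cat in CATEGORIES:
        called = confusion[cat].sum()
        correct = sum(
            confusion.loc[arch, cat]
            for arch, expected in EXPECTED_CALL.items()
            if expected == cat
        )
        prec[cat] = float(correct / called) if called else np.nan
    return RecoveryReport(
        confusion=confusion,
        sensitivity=pd.Series(sens, name="sensitivity"),
        precision=pd.Series(prec, name="precision"),
    )


@dataclass
class GeneReport:
    """Per-gene expression summary for boxplot-style reporting."""

    gene_id: str
    per_sample: pd.DataFrame  # sample_id, group, measure, value
    summary: pd.DataFrame  # group x measure: n, median, q1, q3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"gene {self.gene_id} ({self.per_sample['unit'].iloc[0]})"]
        for (group, measure), row in self.summary.iterrows():
            lines.append(
                f"  {group:9s} {measure:8s} n={int(row['n'])} "
                f"median={row['median']:.1f} IQR=[{row['q1']:.1f}, {row['q3']:.1f}]"
            )
        return "\n".join(lines)


def gene_report(gene_id: str, norm: NormalizedMatrix) -> GeneReport:
    """Per-group normalized expression of one gene: parental totals, hybrid
    totals and hybrid per-allele values, with group medians and IQRs."""
    if gene_id not in norm.values.index:
        raise SchemaError(
            f"gene {gene_id!r} is not in the normalized table (removed by the "
            "minimum-read filter or never present)"
        )
    unit = "CPM" if norm.method == "cpm" else "normalized counts"
    totals = norm.total_expression().loc[gene_id]
    rows = []
    for _, srow in norm.meta.iterrows():
        sid, group = srow["sample_id"], srow["group"]
        rows.append(
            {"sample_id": sid, "group": group, "measure": "total",
             "value": float(totals[sid]), "unit": unit}
        )
        if group == "hybrid":
            for allele in ("species1", "species2"):
                rows.append(
                    {"sample_id": sid, "group": group,
                     "measure": f"allele_{allele}",
                     "value": float(norm.values.loc[gene_id, (sid, allele)]),
                     "unit": unit}
                )
    per_sample = pd.DataFrame(rows)
    summary = (
        per_sample.groupby(["group", "measure"])["value"]
        .agg(
            n="count",
            median="median",
            q1=lambda v: v.quantile(0.25),
            q3=lambda v: v.quantile(0.75),
        )
    )
    return GeneReport(gene_id=gene_id, per_sample=per_sample, summary=summary)
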