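"""DGE/ASE testing, the cis/trans rule, the ASE-vs-DGE regression, recovery
scoring and per-gene reports."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hybridase import (
    AnalysisSettings,
    SchemaError,
    SimulationConfig,
    analyze_stratum,
    ase_dge_regression,
    ase_test,
    classify,
    dge_test,
    filter_min_reads,
    gene_report,
    normalize,
    recovery_metrics,
    run_pipeline,
    simulate_experiment,
)


def _classify_one(padj_dge, padj_ase, fc_dge, fc_ase, alpha=0.05):
    dge = pd.DataFrame({"log2fc_dge": [fc_dge], "padj_dge": [padj_dge]},
                       index=["g"])
    ase = pd.DataFrame({"log2fc_ase": [fc_ase], "padj_ase": [padj_ase]},
                       index=["g"])
    return classify(dge, ase, alpha=alpha)["category"].iloc[0]


def test_classify_worked_cells():
    # both significant, same direction -> cis
    assert _classify_one(0.01, 0.01, 1.0, 0.5) == "cis"
    # significant only for DGE -> trans
    assert _classify_one(0.01, 0.20, 1.0, 0.1) == "trans"
    # neither significant -> conserved
    assert _classify_one(0.30, 0.30, 1.0, 1.0) == "conserved"


def test_classify_exhaustive_truth_table():
    """Hand-enumerated truth table over all {sig, not-sig}^2 x sign cells."""
    alpha = 0.05
    sig, notsig = 0.01, 0.5
    for (p_d, p_a, s_d, s_a) in itertools.product(
        (sig, notsig), (sig, notsig), (-1.0, 0.0, 1.0), (-1.0, 0.0, 1.0)
    ):
        got = _classify_one(p_d, p_a, s_d, s_a, alpha)
        dge_sig = p_d < alpha
        ase_sig = p_a < alpha
        if dge_sig and ase_sig:
            if s_d == s_a and s_d != 0.0:
                expected = "cis"
            else:
                expected = "ambiguous"  # opposite signs or a sign tie
        elif dge_sig:
            expected = "trans"
        elif ase_sig:
            expected = "ambiguous"  # ASE without DGE: outside the rule
        else:
            expected = "conserved"
        assert got == expected, (p_d, p_a, s_d, s_a)


def test_classify_partitions_gene_set(small_experiment):
    counts, meta, _ = small_experiment
    res = run_pipeline(counts, meta).results
    assert res["category"].isin(["cis", "trans", "conserved", "ambiguous"]).all()


def test_classify_boundary_alpha_is_strict():
    # padj exactly alpha is NOT significant (padj < alpha)
    assert _classify_one(0.05, 0.01, 1.0, 1.0) == "ambiguous"
    assert _classify_one(0.01, 0.05, 1.0, 1.0) == "trans"


def test_classify_missing_padj_errors():
    dge = pd.DataFrame({"log2fc_dge": [1.0], "padj_dge": [np.nan]}, index=["g"])
    ase = pd.DataFrame({"log2fc_ase": [1.0], "padj_ase": [0.01]}, index=["g"])
    with pytest.raises(SchemaError, match="padj"):
        classify(dge, ase)


def _norm(counts, meta):
    filtered, _ = filter_min_reads(counts, meta)
    return normalize(filtered, meta, size_factor_source=counts)


def test_dge_invariant_to_within_group_sample_order(small_experiment):
    counts, meta, _ = small_experiment
    norm = _norm(counts, meta)
    base = dge_test(norm)
    shuffled = meta.copy()
    s1 = shuffled[shuffled["group"] == "species1"].iloc[::-1]
    shuffled = pd.concat(
        [s1, shuffled[shuffled["group"] != "species1"]]
    ).reset_index(drop=True)
    norm2 = _norm(counts, shuffled)
    permuted = dge_test(norm2)
    pd.testing.assert_series_equal(base["p_dge"], permuted["p_dge"])
    pd.testing.assert_series_equal(base["log2fc_dge"], permuted["log2fc_dge"])


def test_dge_and_ase_recover_strong_cis_gene():
    cfg = SimulationConfig(
        n_genes=300,
        architecture_fractions={"cis_only": 0.3, "conserved": 0.7},
        nb_dispersion=0.01,
        library_sizes=2e6,
        seed=21,
    )
    counts, meta, truth = simulate_experiment(cfg)
    norm = _norm(counts, meta)
    dge = dge_test(norm)
    ase = ase_test(norm)
    merged = truth.set_index("gene_id").join(dge).join(ase)
    cis = merged[merged["architecture"] == "cis_only"]
    np.testing.assert_allclose(cis["log2fc_dge"], cis["c"], atol=0.35)
    np.testing.assert_allclose(cis["log2fc_ase"], cis["c"], atol=0.35)
    trans_like = merged[merged["architecture"] == "conserved"]
    assert np.abs(trans_like["log2fc_ase"]).max() < 0.35


def test_ase_balanced_for_trans_genes():
    cfg = SimulationConfig(
        n_genes=300,
        architecture_fractions={"trans_only": 0.3, "conserved": 0.7},
        nb_dispersion=0.01,
        library_sizes=2e6,
        seed=22,
    )
    counts, meta, truth = simulate_experiment(cfg)
    norm = _norm(counts, meta)
    ase = ase_test(norm)
    merged = truth.set_index("gene_id").join(ase)
    trans = merged[merged["architecture"] == "trans_only"]
    # "balanced levels in an F1 hybrid": allelic ratio ~ 0 despite |t| = 2
    assert np.abs(trans["log2fc_ase"]).max() < 0.35
    assert abs(trans["log2fc_ase"].mean()) < 0.05


def test_regression_identity_line():
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "log2fc_dge": np.linspace(-2, 2, 10),
            "log2fc_ase": np.linspace(-2, 2, 10),
        }
    )
    reg = ase_dge_regression(df)
    assert reg.slope == pytest.approx(1.0)
    assert reg.intercept == pytest.approx(0.0, abs=1e-12)
    assert reg.r2 == pytest.approx(1.0)
    assert reg.p_value == 0.0


def test_regression_flat_response():
    df = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "log2fc_dge": [0.0, 1.0, 2.0, 3.0],
            "log2fc_ase": [0.7, 0.7, 0.7, 0.7],
        }
    )
    reg = ase_dge_regression(df)
    assert reg.slope == 0.0
    assert reg.r2 == 0.0


def test_regression_matches_scipy_linregress():
    rng = np.random.default_rng(5)
    x = rng.normal(size=200)
    y = 0.6 * x + rng.normal(scale=0.5, size=200)
    df = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(200)], "log2fc_dge": x, "log2fc_ase": y}
    )
    reg = ase_dge_regression(df)
    ref = sps.linregress(x, y)
    assert reg.slope == pytest.approx(ref.slope, rel=1e-12)
    assert reg.intercept == pytest.approx(ref.intercept, rel=1e-12)
    assert reg.r2 == pytest.approx(ref.rvalue**2, rel=1e-12)
    assert reg.p_value == pytest.approx(ref.pvalue, rel=1e-9)
    n = 200
    assert reg.adj_r2 == pytest.approx(1 - (1 - reg.r2) * (n - 1) / (n - 2))


def test_regression_scale_equivariance():
    rng = np.random.default_rng(6)
    x = rng.normal(size=50)
    y = x + rng.normal(scale=0.3, size=50)
    df = pd.DataFrame({"gene_id": range(50), "log2fc_dge": x, "log2fc_ase": y})
    df_scaled = df.assign(log2fc_dge=3.0 * x, log2fc_ase=3.0 * y)
    a, b = ase_dge_regression(df), ase_dge_regression(df_scaled)
    assert a.slope == pytest.approx(b.slope)
    assert a.r2 == pytest.approx(b.r2)


def test_regression_degenerate_x_errors():
    df = pd.DataFrame(
        {"gene_id": ["a", "b", "c"], "log2fc_dge": [1.0, 1.0, 1.0],
         "log2fc_ase": [0.0, 0.5, 1.0]}
    )
    with pytest.raises(ValueError, match="variance"):
        ase_dge_regression(df)


def test_recovery_perfect_labeling():
    truth = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "architecture": ["conserved", "cis_only", "trans_only", "cis_plus_trans"],
        }
    )
    calls = pd.DataFrame(
        {"gene_id": ["a", "b", "c", "d"],
         "category": ["conserved", "cis", "trans", "cis"]}
    )
    rep = recovery_metrics(truth, calls)
    assert rep.sensitivity[["conserved", "cis_only", "trans_only",
                            "cis_plus_trans"]].tolist() == [1.0, 1.0, 1.0, 1.0]
    assert rep.confusion.to_numpy().sum() == 4
    assert rep.confusion.loc["cis_only", "cis"] == 1


def test_recovery_row_sums_match_truth(small_experiment):
    counts, meta, truth = small_experiment
    res = run_pipeline(counts, meta).results
    rep = recovery_metrics(truth, res)
    tested = truth[truth["gene_id"].isin(res["gene_id"])]
    expected_rows = tested["architecture"].value_counts()
    for arch in rep.confusion.index:
        assert rep.confusion.loc[arch].sum() == expected_rows.get(arch, 0)
    rates = pd.concat([rep.sensitivity.dropna(), rep.precision.dropna()])
    assert ((rates >= 0) & (rates <= 1)).all()


def test_recovery_mismatched_genes_error():
    truth = pd.DataFrame({"gene_id": ["a"], "architecture": ["conserved"]})
    calls = pd.DataFrame({"gene_id": ["zzz"], "category": ["conserved"]})
    with pytest.raises(SchemaError, match="zzz"):
        recovery_metrics(truth, calls)


def test_all_conserved_type1_call_rate():
    cfg = SimulationConfig(
        n_genes=2000,
        architecture_fractions={"conserved": 1.0},
        nb_dispersion=0.1,
        library_sizes=2e6,
        seed=13,
    )
    counts, meta, truth = simulate_experiment(cfg)
    res = run_pipeline(counts, meta).results
    frac_called = res["category"].isin(["cis", "trans"]).mean()
    assert frac_called <= 0.07


def test_gene_report_shape_and_groups(small_experiment):
    counts, meta, _ = small_experiment
    filtered, _ = filter_min_reads(counts, meta)
    norm = normalize(filtered, meta, method="cpm", size_factor_source=counts)
    gene = filtered.index[0]
    rep = gene_report(gene, norm)
    per = rep.per_sample
    totals = per[per["measure"] == "total"]
    assert totals.groupby("group").size().to_dict() == {
        "species1": 6, "species2": 5, "hybrid": 6
    }
    alleles = per[per["measure"] != "total"]
    assert len(alleles) == 12  # 6 hybrids x 2 alleles
    assert set(rep.summary.index.get_level_values("group")) == {
        "species1", "species2", "hybrid"
    }


def test_gene_report_conserved_gene_groups_agree():
    cfg = SimulationConfig(
        n_genes=400,
        architecture_fractions={"conserved": 1.0},
        nb_dispersion=0.0,
        library_sizes=5e6,
        seed=17,
    )
    counts, meta, _ = simulate_experiment(cfg)
    filtered, _ = filter_min_reads(counts, meta)
    norm = normalize(filtered, meta, method="cpm", size_factor_source=counts)
    gene = filtered.index[0]
    rep = gene_report(gene, norm)
    medians = rep.summary.xs("total", level="measure")["median"]
    spread = medians.max() / medians.min()
    assert spread < 1.2  # parents and hybrids agree within sampling noise


def test_gene_report_filtered_gene_errors(small_experiment):
    counts, meta, _ = small_experiment
    filtered, _ = filter_min_reads(counts, meta)
    norm = normalize(filtered, meta, method="cpm", size_factor_source=counts)
    with pytest.raises(SchemaError, match="filter"):
        gene_report("no_such_gene", norm)


def test_analyze_stratum_requires_two_replicates(toy_counts, toy_meta):
    meta = toy_meta[toy_meta["sample_id"] != "hybrid_2"]
    counts = toy_counts.drop(columns=["hybrid_2"], level=0)
    with pytest.raises(SchemaError, match="hybrid"):
        analyze_stratum(counts, meta, ("legs", "after"))
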