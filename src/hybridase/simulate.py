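"""Synthetic allele-resolved count generator with known cis/trans truth.

The generative model
--------------------
Each gene ``g`` gets a baseline expression ``mu_g`` (log-normal) and a
regulatory architecture with a cis effect ``c`` and a trans effect ``t``
in log2 units.  Expected expression per sample class:

* species1 sample:        ``mu_g``
* species2 sample:        ``mu_g * 2**(c + t)``
* hybrid, species1 allele: ``(mu_g / 2) * 2**(t * h)``
* hybrid, species2 allele: ``(mu_g / 2) * 2**(c + t * h)``

with ``h = hybrid_trans_share``.  Both hybrid alleles sit in the same
trans-acting environment, so the expected hybrid allelic log2 ratio
(species2 allele minus species1 allele) is exactly ``c``, while the
expected species log2 ratio is ``c + t`` — the dichotomy that lets an F1
hybrid separate cis- from trans-regulatory divergence: a purely trans
difference collapses to balanced alleles in the hybrid, a cis difference
persists as allelic imbalance.

Per sample, expected expression is renormalized to relative abundance and
scaled to the library size; counts are independent negative-binomial draws
(``var = mu + alpha * mu**2``).  Parental reads map cleanly to the
own-species ortholog column of the composite-genome layout; the opposite
column is zero.  ``mapping_bias`` multiplies species-1-allele means before
drawing to emulate imperfect read assignment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ARCHITECTURES, ConfigError, SimulationConfig

__all__ = [
    "simulate_experiment",
    "expected_log2_ratios",
    "make_ortholog_map",
]

ORTHOLOGS = ("species1", "species2")

TRUTH_COLUMNS = [
    "gene_id",
    "architecture",
    "c",
    "t",
    "expected_dge",
    "expected_ase",
]


def _allocate_architectures(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Assign architectures in exact proportion (largest-remainder), then
    shuffle so architecture is independent of baseline expression."""
    fracs = {a: config.architecture_fractions.get(a, 0.0) for a in ARCHITECTURES}
    raw = {a: f * config.n_genes for a, f in fracs.items()}
    counts = {a: int(np.floor(v)) for a, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    remainders = sorted(
        ARCHITECTURES, key=lambda a: (raw[a] - counts[a], a), reverse=True
    )
    for a in remainders[:short]:
        counts[a] += 1
    labels = np.repeat(
        [a for a in ARCHITECTURES], [counts[a] for a in ARCHITECTURES]
    )
    return rng.permutation(labels)


def _draw_magnitudes(
    config: SimulationConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    mag = config.effect_magnitude
    if isinstance(mag, tuple):
        return rng.uniform(mag[0], mag[1], size=size)
    return np.full(size, float(mag))


def _draw_effects(
    config: SimulationConfig, architectures: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = len(architectures)
    c = np.zeros(n)
    t = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], size=n)
    mags_c = _draw_magnitudes(config, n, rng)
    mags_t = _draw_magnitudes(config, n, rng)
    is_cis = architectures == "cis_only"
    is_trans = architectures == "trans_only"
    is_both = architectures == "cis_plus_trans"
    is_comp = architectures == "compensatory"
    c[is_cis] = signs[is_cis] * mags_c[is_cis]
    t[is_trans] = signs[is_trans] * mags_t[is_trans]
    # cis_plus_trans: same sign so effects reinforce (c*t > 0)
    c[is_both] = signs[is_both] * mags_c[is_both]
    t[is_both] = signs[is_both] * mags_t[is_both]
    # compensatory: equal magnitude, opposite sign, so c + t = 0 exactly
    c[is_comp] = signs[is_comp] * mags_c[is_comp]
    t[is_comp] = -c[is_comp]
    return c, t


def _make_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for group, n_rep in zip(("species1", "species2", "hybrid"), config.replicates):
        for r in range(1, n_rep + 1):
            rows.append(
                {
                    "sample_id": f"{group}_{r}",
                    "group": group,
                    "tissue": config.tissue,
                    "stage": config.stage,
                    "replicate": r,
                }
            )
    return pd.DataFrame(rows)


def _nb_draw(
    mean: np.ndarray, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha == 0.0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    # var = mu + alpha*mu^2  <=>  NB(n=1/alpha, p=n/(n+mu))
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one stratum of an interspecific hybrid ASE experiment.

    Returns
    -------
    counts:
        Genes x (sample, ortholog) integer count table.  Hybrid samples
        carry reads in both ortholog columns; parental samples only in
        their own-species column.
    metadata:
        One row per sample: sample_id, group, tissue, stage, replicate.
    truth:
        Per-gene architecture, ``c``, ``t``, ``expected_dge`` (= c + t,
        species2 over species1) and ``expected_ase`` (= c).

    The same config (including seed) is guaranteed to reproduce identical
    tables bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i + 1:0{width}d}" for i in range(n)])

    log2_mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    mu = np.exp2(log2_mu)
    architectures = _allocate_architectures(config, rng)
    c, t = _draw_effects(config, architectures, rng)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "architecture": architectures,
            "c": c,
            "t": t,
            "expected_dge": c + t,
            "expected_ase": c,
        }
    )

    h = config.hybrid_trans_share
    expr_s1 = mu
    expr_s2 = mu * np.exp2(c + t)
    expr_h1 = (mu / 2.0) * np.exp2(t * h)
    expr_h2 = (mu / 2.0) * np.exp2(c + t * h)

    rel_s1 = expr_s1 / expr_s1.sum()
    rel_s2 = expr_s2 / expr_s2.sum()
    denom_h = (expr_h1 + expr_h2).sum()
    rel_h1 = expr_h1 / denom_h
    rel_h2 = expr_h2 / denom_h

    meta = _make_metadata(config)
    libs = config.per_sample_library_sizes()
    alpha = config.nb_dispersion
    bias = config.mapping_bias

    columns = pd.MultiIndex.from_product(
        [meta["sample_id"], list(ORTHOLOGS)], names=["sample", "ortholog"]
    )
    counts = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene_id"), columns=columns, dtype=np.int64
    )

    for (_, row), lib in zip(meta.iterrows(), libs):
        sid, group = row["sample_id"], row["group"]
        if group == "species1":
            counts[(sid, "species1")] = _nb_draw(rel_s1 * lib * bias, alpha, rng)
        elif group == "species2":
            counts[(sid, "species2")] = _nb_draw(rel_s2 * lib, alpha, rng)
        else:  # hybrid: two independent NB draws, one per allele
            counts[(sid, "species1")] = _nb_draw(rel_h1 * lib * bias, alpha, rng)
            counts[(sid, "species2")] = _nb_draw(rel_h2 * lib, alpha, rng)

    return counts, meta, truth


def expected_log2_ratios(truth: pd.DataFrame) -> pd.DataFrame:
    """Oracle expectations per gene: ``expected_dge = c + t`` (the species
    log2 ratio) and ``expected_ase = c`` (the hybrid allelic log2 ratio)."""
    if len(truth) == 0:
        raise ConfigError("truth table is empty")
    out = pd.DataFrame(
        {
            "expected_dge": truth["c"].to_numpy() + truth["t"].to_numpy(),
            "expected_ase": truth["c"].to_numpy(),
        },
        index=pd.Index(truth["gene_id"], name="gene_id"),
    )
    return out


def make_ortholog_map(gene_ids) -> pd.DataFrame:
    """Ortholog pairing table for simulated genes: one unified id mapped to
    a per-species gene id, emulating the composite-genome gene pairing."""
    gene_ids = list(gene_ids)
    return pd.DataFrame(
        {
            "unified_gene_id": gene_ids,
            "species1_gene_id": [f"{g}_sp1" for g in gene_ids],
            "species2_gene_id": [f"{g}_sp2" for g in gene_ids],
        }
    )
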