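"""Configuration objects for the simulator and the analysis pipeline.

Configuration can be built directly in Python or loaded from a YAML/JSON
file.  Validation is strict: every error names the offending field so that
misconfigured runs fail before any random number is drawn.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

#: Ground-truth regulatory architectures the simulator can assign to a gene.
ARCHITECTURES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_plus_trans",
    "compensatory",
)

GROUPS = ("species1", "species2", "hybrid")


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def _default_fractions() -> dict[str, float]:
    # A realistic bulk-RNA-seq mixture: most genes conserved, cis and trans
    # divergence each common, combined and compensatory architectures rarer.
    return {
        "conserved": 0.60,
        "cis_only": 0.15,
        "trans_only": 0.15,
        "cis_plus_trans": 0.05,
        "compensatory": 0.05,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated hybrid-ASE experiment.

    Attributes
    ----------
    n_genes:
        Number of ortholog pairs to simulate.
    architecture_fractions:
        Proportion of genes per regulatory architecture; must sum to 1.
    effect_magnitude:
        |c| and/or |t| in log2 units: a single float for a fixed magnitude
        or a ``(low, high)`` pair for a uniform draw.  Signs are random.
    baseline_log2_mean, baseline_log2_sd:
        Per-gene baseline expression is log-normal:
        ``log2(mu_g) ~ Normal(mean, sd)``.  Only the shape matters because
        per-sample abundances are renormalized to the library size.
    nb_dispersion:
        Negative-binomial dispersion alpha with ``var = mu + alpha*mu**2``;
        ``alpha = 0`` degenerates to Poisson.
    library_sizes:
        Reads per sample: one value for all samples or one value per sample
        in metadata order (species1 replicates, species2, hybrids).
    replicates:
        ``(n_species1, n_species2, n_hybrid)``; each group needs >= 2
        replicates so downstream tests have a variance.
    hybrid_trans_share:
        Fraction of the trans effect active in the hybrid trans environment
        (0.5 makes total hybrid expression intermediate between parents).
    mapping_bias:
        Multiplicative factor applied to all species-1-allele (and
        species-1-sample) expected counts; 1.0 is unbiased read assignment.
    seed:
        Integer seed; identical configs produce byte-identical tables.
    tissue, stage:
        Labels for the single stratum this experiment represents.
    """

    n_genes: int = 1000
    architecture_fractions: Mapping[str, float] = field(
        default_factory=_default_fractions
    )
    effect_magnitude: Union[float, tuple[float, float]] = 2.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.1
    library_sizes: Union[float, Sequence[float]] = 2e6
    replicates: tuple[int, int, int] = (6, 5, 6)
    hybrid_trans_share: float = 0.5
    mapping_bias: float = 1.0
    seed: int = 0
    tissue: str = "legs"
    stage: str = "after"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        unknown = set(self.architecture_fractions) - set(ARCHITECTURES)
        if unknown:
            raise ConfigError(
                f"architecture_fractions has unknown labels {sorted(unknown)}; "
                f"allowed: {list(ARCHITECTURES)}"
            )
        total = sum(self.architecture_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"architecture_fractions must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.architecture_fractions.values()):
            raise ConfigError("architecture_fractions must be non-negative")
        mag = self.effect_magnitude
        if isinstance(mag, (tuple, list)):
            if len(mag) != 2 or mag[0] > mag[1] or mag[0] <= 0:
                raise ConfigError(
                    f"effect_magnitude range must be 0 < low <= high, got {mag}"
                )
        elif mag <= 0:
            raise ConfigError(f"effect_magnitude must be > 0, got {mag}")
        if self.baseline_log2_sd < 0:
            raise ConfigError("baseline_log2_sd must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigError(
                f"nb_dispersion must be >= 0, got {self.nb_dispersion}"
            )
        if len(self.replicates) != 3:
            raise ConfigError(
                "replicates must be (n_species1, n_species2, n_hybrid)"
            )
        for grp, n in zip(GROUPS, self.replicates):
            if n < 2:
                raise ConfigError(
                    f"replicates: group {grp!r} needs >= 2 replicates, got {n}"
                )
        libs = self.library_sizes
        if isinstance(libs, (int, float)):
            if libs < 1:
                raise ConfigError(f"library_sizes must be >= 1, got {libs}")
        else:
            if len(libs) != self.n_samples:
                raise ConfigError(
                    f"library_sizes: expected {self.n_samples} per-sample "
                    f"values, got {len(libs)}"
                )
            if any(v < 1 for v in libs):
                raise ConfigError("library_sizes values must all be >= 1")
        if not 0.0 <= self.hybrid_trans_share <= 1.0:
            raise ConfigError(
                f"hybrid_trans_share must be in [0, 1], got "
                f"{self.hybrid_trans_share}"
            )
        if self.mapping_bias <= 0:
            raise ConfigError(
                f"mapping_bias must be > 0, got {self.mapping_bias}"
            )

    def per_sample_library_sizes(self) -> list[float]:
        if isinstance(self.library_sizes, (int, float)):
            return [float(self.library_sizes)] * self.n_samples
        return [float(v) for v in self.library_sizes]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "replicates" in d:
            d["replicates"] = tuple(d["replicates"])
        if "effect_magnitude" in d and isinstance(
            d["effect_magnitude"], (list, tuple)
        ):
            d["effect_magnitude"] = tuple(d["effect_magnitude"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        """Load from YAML (or JSON, a YAML subset)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["architecture_fractions"] = dict(self.architecture_fractions)
        d["replicates"] = list(self.replicates)
        if isinstance(self.effect_magnitude, tuple):
            d["effect_magnitude"] = list(self.effect_magnitude)
        if not isinstance(self.library_sizes, (int, float)):
            d["library_sizes"] = list(self.library_sizes)
        return d


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunable knobs of the analysis pipeline.

    ``min_reads``/``filter_mode`` control the per-stratum gene filter,
    ``norm_method`` the library-size normalization (``median_of_ratios``
    DESeq-style size factors, or plain ``cpm``), ``size_factor_refine``
    whether a second pass anchors median-of-ratios factors to genes with
    no DGE evidence (removes the composition offset a directional
    imbalance of divergent genes leaves in the median), ``size_factors_from``
    whether library sizes come from the unfiltered or the filtered table,
    ``pseudocount`` the offset inside log2, ``alpha`` the padj cutoff of
    the cis/trans rule, and ``reference`` the group subtracted when forming
    log2 fold changes (positive log2FC = higher in the other species).
    """

    min_reads: int = 10
    filter_mode: str = "sum"
    norm_method: str = "median_of_ratios"
    size_factor_refine: bool = True
    size_factors_from: str = "unfiltered"
    pseudocount: float = 1.0
    alpha: float = 0.05
    reference: str = "species1"

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ConfigError(f"min_reads must be >= 0, got {self.min_reads}")
        if self.filter_mode not in ("sum", "each"):
            raise ConfigError(
                f"filter_mode must be 'sum' or 'each', got {self.filter_mode!r}"
            )
        if self.norm_method not in ("median_of_ratios", "cpm"):
            raise ConfigError(
                "norm_method must be 'median_of_ratios' or 'cpm', "
                f"got {self.norm_method!r}"
            )
        if self.size_factors_from not in ("unfiltered", "filtered"):
            raise ConfigError(
                "size_factors_from must be 'unfiltered' or 'filtered', "
                f"got {self.size_factors_from!r}"
            )
        if self.pseudocount <= 0:
            raise ConfigError(
                f"pseudocount must be > 0, got {self.pseudocount}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reference not in ("species1", "species2"):
            raise ConfigError(
                f"reference must be 'species1' or 'species2', "
                f"got {self.reference!r}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisSettings":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown analysis settings: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()
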