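import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hybridase import SimulationConfig, simulate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = SimulationConfig(
    n_genes=200,
    architecture_fractions={
        "conserved": 0.4,
        "cis_only": 0.2,
        "trans_only": 0.2,
        "cis_plus_trans": 0.1,
        "compensatory": 0.1,
    },
    nb_dispersion=0.05,
    library_sizes=5e5,
    seed=7,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A small mixed-architecture experiment shared across tests."""
    return simulate_experiment(SMALL_CONFIG)


@pytest.fixture()
def toy_counts():
    """Hand-written 3-gene table: 2 parental samples per species, 2 hybrids."""
    samples = ["species1_1", "species1_2", "species2_1", "species2_2",
               "hybrid_1", "hybrid_2"]
    cols = pd.MultiIndex.from_product(
        [samples, ["species1", "species2"]], names=["sample", "ortholog"]
    )
    data = np.zeros((3, 12), dtype=np.int64)
    # genes x (sample, allele); parental reads only on the own ortholog
    data[0] = [100, 0, 120, 0, 0, 200, 0, 180, 60, 50, 70, 40]
    data[1] = [30, 0, 25, 0, 0, 40, 0, 35, 20, 15, 25, 10]
    data[2] = [9, 0, 50, 0, 0, 50, 0, 50, 30, 30, 30, 30]
    return pd.DataFrame(data, index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
                        columns=cols)


@pytest.fixture()
def toy_meta():
    rows = []
    for group, n in (("species1", 2), ("species2", 2), ("hybrid", 2)):
        for r in range(1, n + 1):
            rows.append({"sample_id": f"{group}_{r}", "group": group,
                         "tissue": "legs", "stage": "after", "replicate": r})
    return pd.DataFrame(rows)
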