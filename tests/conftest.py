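import numpy as np
import pandas as pd
import pytest

from cernet.de import differential_expression, sample_separation_report
from cernet.evaluate import recovery_rates
from cernet.simulate import SimulationConfig, generate_dataset, null_config

# fixed bases so every run of the suite sees the same simulated cohorts
MULTISEED_BASE = 20101
NULL_BASE = 40201
N_SEEDS = 50


@pytest.fixture(scope="session")
def default_multiseed():
    """Recovery rates of the full chain over 50 default-config seeds."""
    return recovery_rates(MULTISEED_BASE, N_SEEDS)


@pytest.fixture(scope="session")
def null_multiseed():
    """Null-config diagnostics: separation ARI on all genes, Welch type-I
    rejection rate, and the pooled null p-value distribution."""
    aris = []
    reject = 0
    tested = 0
    pooled_p = []
    for i in range(N_SEEDS):
        dataset = generate_dataset(null_config(seed=NULL_BASE + i))
        rep = sample_separation_report(dataset.tables, dataset.groups)
        aris.append({cls: r.ari for cls, r in rep.items()})
        for table in dataset.tables.values():
            de = differential_expression(table, dataset.groups)
            p = de["p_value"].to_numpy()
            reject += int((p <= 0.05).sum())
            tested += len(p)
            pooled_p.append(p)
    return {
        "aris": aris,
        "type1_rate": reject / tested,
        "pooled_p": np.concatenate(pooled_p),
    }


@pytest.fixture()
def small_dataset():
    """One small default-config synthetic dataset."""
    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture()
def toy_de_records():
    """Five genes exercising every branch of the DE screening rule."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(1, 6)],
            "rna_class": ["mRNA"] * 5,
            "mean_case": [1.0] * 5,
            "mean_control": [1.0] * 5,
            "log2fc": [1.2, -1.5, 0.3, 2.0, -0.9],
            "p_value": [0.01, 0.04, 0.01, 0.20, 0.03],
            "q_value": [0.03, 0.05, 0.02, 0.30, 0.04],
            "direction": ["up", "down", "up", "up", "down"],
            "degenerate": [False] * 5,
        }
    )
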