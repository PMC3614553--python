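import numpy as np
import pandas as pd
import pytest

from poolsig import SimConfig, generate_cohorts


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic study (4 cohorts, 2000 genes, 20 signal)."""
    cfg = SimConfig(seed=1)
    bundles, truth, probe_map = generate_cohorts(cfg)
    return cfg, bundles, truth, probe_map


@pytest.fixture(scope="session")
def tiny_sim():
    """Small, fast study used by structural tests."""
    cfg = SimConfig(
        n_cohorts=2,
        subjects_per_cohort=(60, 60),
        n_genes=120,
        n_signal_genes=8,
        probes_per_gene_range=(1, 4),
        cohort_transforms=((1.0, 0.0), (2.2, -8.0)),
        seed=11,
    )
    bundles, truth, probe_map = generate_cohorts(cfg)
    return cfg, bundles, truth, probe_map


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_clinical(n, **overrides):
    """Minimal well-formed clinical table for exclusion-cascade tests."""
    base = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "cohort": "c1",
            "age": 55.0,
            "tumor_size": 2.0,
            "grade": 2,
            "er_status": 1,
            "node_status": 0.0,
            "relapse_event": 0.0,
            "time_years": 10.0,
        }
    )
    for col, vals in overrides.items():
        base[col] = vals
    return base
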