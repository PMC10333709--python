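import numpy as np
import pandas as pd
import pytest

from cellpool import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two runs of 5 pooled donors, 120 cells/donor, 60 SNPs."""
    cfg = SimulationConfig(n_runs=2, donors_per_run=5, cells_per_donor=120,
                           n_snps=60, depth_mean=20.0, doublet_rate=0.05,
                           seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def paired_design():
    """30 donors, two timepoints each, one group."""
    return pd.DataFrame([
        {"donor_id": f"d{i:02d}", "group": "allergic", "timepoint": tp}
        for i in range(30) for tp in ("before", "after")
    ])


def make_cluster_params(beta1, sigma_u=0.5, sigma_e=0.3, beta0=-2.0,
                        cluster_id="c1"):
    return pd.DataFrame({
        "cluster_id": [cluster_id], "beta0": [beta0], "beta1": [beta1],
        "sigma_u": [sigma_u], "sigma_e": [sigma_e],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
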