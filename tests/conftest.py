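import numpy as np
import pandas as pd
import pytest

from netsig.synthcohort import SimulationConfig, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused by read-only tests."""
    cfg = SimulationConfig(seed=7, n_samples=250, n_genes=30, n_clusters=2)
    return make_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def sem_dataset(n_genes=15, n=2000, edge_prob=0.2, seed=0, noise_sd=1.0, w=(0.5, 1.0)):
    """Plain linear-Gaussian SEM sample on a random DAG (no counts, no
    instruments); returns (expression genes x samples DataFrame, true DAG)."""
    from netsig.synthcohort import SimulationConfig, simulate_true_dag

    cfg = SimulationConfig(
        seed=seed,
        n_samples=n,
        n_genes=n_genes,
        n_clusters=1,
        edge_prob=edge_prob,
        weight_range=w,
        noise_sd=noise_sd,
    )
    dag = simulate_true_dag(cfg)
    rng = np.random.default_rng(seed + 100)
    idx = {g: i for i, g in enumerate(dag.genes)}
    X = np.zeros((n_genes, n))
    for g in dag.genes:
        val = rng.normal(0, noise_sd, size=n)
        for parent, wgt in dag.parents(g):
            val += wgt * X[idx[parent]]
        X[idx[g]] = val
    return pd.DataFrame(X, index=list(dag.genes), columns=[f"S{i}" for i in range(n)]), dag
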