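import numpy as np
import pandas as pd
import pytest

from netmark import fixtures
from netmark.datasets import ExpressionDataset
from netmark.network import RegulatoryNetwork
from netmark.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def candidate_net() -> RegulatoryNetwork:
    """The nine-miRNA worked-example subnetwork with pinned TF flags."""
    return fixtures.candidate_network()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down synthetic study for fast unit tests."""
    return SyntheticConfig(
        n_mirnas=30,
        n_genes=150,
        n_tfs=40,
        n_case_mirna=10,
        n_control_mirna=10,
        n_case_mrna=8,
        n_control_mrna=8,
        n_planted_biomarkers=2,
        n_gene_sets=20,
        gene_set_size=10,
        seed=11,
    )


def make_dataset(
    n_features: int,
    n_case: int,
    n_control: int,
    seed: int = 0,
    noise_sd: float = 0.5,
    shift: float = 0.0,
    n_shifted: int = 0,
) -> ExpressionDataset:
    """Plain two-group normal dataset; the first ``n_shifted`` features get +shift in cases."""
    rng = np.random.default_rng(seed)
    vals = 8.0 + noise_sd * rng.standard_normal((n_features, n_case + n_control))
    vals[:n_shifted, :n_case] += shift
    cols = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_control)]
    return ExpressionDataset(
        values=pd.DataFrame(vals, index=[f"f{i:04d}" for i in range(n_features)], columns=cols),
        design=pd.Series(["case"] * n_case + ["control"] * n_control, index=cols),
    )


def random_network(rng: np.random.Generator, n_mirnas: int = 8, n_genes: int = 20) -> RegulatoryNetwork:
    """Random bipartite network for property checks (small enough to brute-force)."""
    mirnas = [f"miR-t-{i}" for i in range(n_mirnas)]
    genes = [f"G{i}" for i in range(n_genes)]
    edges = set()
    for m in mirnas:
        k = int(rng.integers(0, n_genes // 2 + 1))
        for g in rng.choice(genes, size=k, replace=False):
            edges.add((m, g))
    tf = frozenset(rng.choice(genes, size=n_genes // 4, replace=False).tolist())
    return RegulatoryNetwork(
        mirna_ids=frozenset(mirnas),
        gene_ids=frozenset(genes),
        edges=frozenset(edges),
        tf_genes=tf,
    )
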