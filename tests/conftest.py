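"""Shared fixtures: small synthetic bundles and a toy GMT collection."""

import numpy as np
import pandas as pd
import pytest

from dnmeta import DatasetSpec, SimulationConfig, generate_multiset
from dnmeta.enrich import GeneSet, write_gmt


@pytest.fixture(scope="session")
def small_config():
    """3 glomerulus + 2 tubule datasets of 10v10, planted |log2FC| = 2."""
    specs = [
        DatasetSpec("glomA", "glomerulus", 10, 10, 0.8, 1.1),
        DatasetSpec("glomB", "glomerulus", 10, 10, -0.5, 0.9),
        DatasetSpec("glomC", "glomerulus", 10, 10, 0.3, 1.0),
        DatasetSpec("tubA", "tubule", 10, 10, -0.9, 1.05),
        DatasetSpec("tubB", "tubule", 10, 10, 0.6, 0.95),
    ]
    return SimulationConfig(
        n_genes=600,
        dataset_specs=specs,
        n_de_genes_per_compartment=50,
        de_log2fc=2.0,
        module_size=20,
        n_outlier_arrays=0,
        n_duplicate_pairs=0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_multiset(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The full nine-dataset study-design bundle with planted artifacts."""
    return generate_multiset(SimulationConfig(seed=7))


@pytest.fixture()
def toy_gmt(tmp_path):
    """Tiny fixture collection over synthetic gene ids (synthetic stand-ins
    echoing renal-development / immune-response themes)."""
    sets = [
        GeneSet("renal_development", "toy kidney development set",
                frozenset(f"G{i:05d}" for i in range(0, 30))),
        GeneSet("humoral_immune_response", "toy immune set",
                frozenset(f"G{i:05d}" for i in range(100, 140))),
        GeneSet("metabolic_regulation", "toy metabolism set",
                frozenset(f"G{i:05d}" for i in range(300, 360))),
    ]
    path = tmp_path / "toy.gmt"
    write_gmt(sets, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_matrix(rng, n_genes=50, n_samples=4, prefix="s"):
    return pd.DataFrame(
        rng.normal(8, 1, (n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{prefix}{j}" for j in range(n_samples)],
    )
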