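"""Shared fixtures: small seeded models and paired tables.

Everything is generated programmatically; session scope keeps the suite
fast since the models are read-only.
"""

import numpy as np
import pytest

import transkingdom as tk


@pytest.fixture(scope="session")
def small_model() -> tk.GroundTruthModel:
    """30-taxon ground truth with an even kingdom split."""
    model = tk.generate_ground_truth(n_taxa=30, seed=7)
    model.validate()
    return model


@pytest.fixture(scope="session")
def small_data(small_model):
    """Abundances and paired reads for the 30-taxon model, 60 samples."""
    return tk.simulate_paired_tables(small_model, 60, seed=7)


@pytest.fixture(scope="session")
def medium_model() -> tk.GroundTruthModel:
    """100-taxon model at the benchmark's scaled-down size."""
    model = tk.generate_ground_truth(n_taxa=100, seed=3)
    model.validate()
    return model


@pytest.fixture
def toy_paired() -> tk.PairedCountTables:
    """Tiny hand-sized paired tables (2+2 taxa, 5 samples)."""
    rng = np.random.default_rng(0)
    return tk.PairedCountTables(
        counts_a=rng.integers(1, 50, size=(5, 2)),
        counts_b=rng.integers(1, 50, size=(5, 2)),
        sample_ids=[f"s{i}" for i in range(5)],
        taxon_ids_a=["a1", "a2"],
        taxon_ids_b=["b1", "b2"],
    )
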