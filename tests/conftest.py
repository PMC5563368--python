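"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pandas as pd
import pytest

from rhizotox.expression import ExpressionDataset
from rhizotox.synthetic import (SyntheticConfig, default_planted_counts,
                                generate_expression)

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random nucleotide sequence."""
    return _DNA[rng.integers(0, 4, size=length, dtype=np.uint8)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20170818)


@pytest.fixture(scope="session")
def noise_free_run():
    """Noise-free synthetic dataset + truth at study-design scale."""
    config = SyntheticConfig(n_genes=2000, planted_counts=default_planted_counts(),
                             noise_sd=0.0, seed=1)
    dataset, truth = generate_expression(config)
    return config, dataset, truth


def tiny_dataset(values_by_sample: dict, meta_rows: list, genes: list
                 ) -> ExpressionDataset:
    """Build a small ExpressionDataset from explicit columns.

    ``meta_rows``: (sample_id, stress, timepoint, replicate, condition).
    """
    values = pd.DataFrame(values_by_sample, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(meta_rows, columns=["sample_id", "stress", "timepoint",
                                               "replicate", "condition"]
                           ).set_index("sample_id")
    return ExpressionDataset(values=values, samples=samples)
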