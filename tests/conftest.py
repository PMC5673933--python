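"""Shared fixtures: a small synthetic study generated once per session."""
from __future__ import annotations

import pytest

from circfield import synthio


@pytest.fixture(scope="session")
def genome():
    return synthio.generate_genome(1, 200_000, rng_seed=17)


@pytest.fixture(scope="session")
def gene_models(genome):
    return synthio.generate_gene_models(genome, 60, rng_seed=17)


@pytest.fixture(scope="session")
def truth(gene_models):
    """Field-effect truth set over the full abundance spectrum."""
    return synthio.generate_truth(gene_models, 50, rng_seed=17)


@pytest.fixture(scope="session")
def high_truth(gene_models):
    """Truth set with uniformly high means, for detector fidelity checks."""
    return synthio.generate_truth(
        gene_models, 10, rng_seed=3, base_mean_log10_range=(1.4, 1.6)
    )


@pytest.fixture(scope="session")
def mirna_resources(genome, gene_models, truth):
    return synthio.generate_mirna_resources(
        genome,
        gene_models,
        truth,
        n_mirna=8,
        planted_sites=[(0, 1), (1, 3)],
        rng_seed=5,
    )
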