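"""Shared fixtures: small simulated datasets reused across test modules."""

import pytest

from aneukit import CountSimParams, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """120 cells x 1200 genes with 20% simple / 5% complex aneuploidy."""
    params = CountSimParams(
        n_cells=120,
        n_genes=1200,
        dispersion=0.1,
        aneuploid_fraction_simple=0.20,
        aneuploid_fraction_complex=0.05,
        seed=7,
    )
    matrix, truths = simulate_counts(params)
    return params, matrix, truths


@pytest.fixture(scope="session")
def euploid_sim():
    """All-euploid matrix for null-behavior tests."""
    params = CountSimParams(
        n_cells=80,
        n_genes=1000,
        dispersion=0.1,
        aneuploid_fraction_simple=0.0,
        aneuploid_fraction_complex=0.0,
        seed=19,
    )
    matrix, truths = simulate_counts(params)
    return params, matrix, truths
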