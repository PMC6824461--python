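import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hicweave.matrix_io import ContactMatrix


def make_matrix(dense, scaffold_bins=None, bin_size=10_000, mask=None, balanced=False):
    """ContactMatrix from a dense symmetric array.

    ``scaffold_bins``: list of (scaffold_id, n_bins); defaults to one
    scaffold spanning all bins.
    """
    dense = np.asarray(dense, dtype=float)
    n = dense.shape[0]
    assert np.allclose(dense, dense.T), "test matrix must be symmetric"
    if scaffold_bins is None:
        scaffold_bins = [("S", n)]
    rows = []
    k = 0
    for sid, nb in scaffold_bins:
        for b in range(nb):
            rows.append((sid, b * bin_size, (b + 1) * bin_size, k))
            k += 1
    assert k == n
    bins = pd.DataFrame(rows, columns=["scaffold_id", "start", "end", "bin_index"])
    return ContactMatrix(bins, sp.csr_matrix(dense), mask=mask, balanced=balanced)


def coverage_matrix(coverage):
    """Diagonal matrix whose row sums equal the given coverage vector."""
    cov = np.asarray(coverage, dtype=float)
    scaffolds = [(f"s{i}", 1) for i in range(len(cov))]
    return make_matrix(np.diag(cov), scaffold_bins=scaffolds)


@pytest.fixture(scope="session")
def small_sim():
    """Two 2-Mb chromosomes at moderate depth: fast shared dataset."""
    from hicweave.synthetic import SimParams, simulate_dataset

    params = SimParams(
        chromosome_lengths=(2_000_000, 2_000_000),
        n_contacts=1_500_000,
        contig_length_min=200_000,
        contig_length_max=600_000,
        seed=11,
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_balanced(small_sim):
    from hicweave import correction

    mask = correction.mad_filter_bins(small_sim.matrix)
    return correction.ice_correct(small_sim.matrix, mask)
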