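import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import cpedscan as cs
from cpedscan.synth import SyntheticTruth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """100 kbp circular genome, one region with a 20 kbp planted period."""
    return SyntheticTruth(
        genome_length=100_000,
        regions=[(0, 100_000, 20_000, 1.0)],
        operons=[(2_000, 6_000, "+"), (30_000, 34_000, "-")],
        structural_rna=[(50_000, 52_000)],
        regulators={"RegA": list(range(0, 100_000, 20_000))},
        factor_seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return cs.simulate_expression(small_truth, n_phases=5, n_replicates=2, noise_sd=0.2, seed=17)


@pytest.fixture(scope="session")
def small_matrix(small_bundle):
    return small_bundle.expression_matrix()


@pytest.fixture(scope="session")
def small_config():
    """Scan configuration shrunk to the 100 kbp fixture genome."""
    return cs.ScanConfig(window=60_000, slide=5_000, period_min=10_000, period_max=35_000,
                         max_lag=40_000, n_randomizations=5)


def random_matrix(n_bins=50, n_cond=5, seed=0, genome_length=None, step=500, mask_bins=()):
    """Unstructured expression matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    g = genome_length or n_bins * step
    grid = cs.BinGrid(g, step, step, circular=True)
    values = rng.gamma(5.0, 20.0, size=(grid.n_bins, n_cond))
    mask = np.zeros(grid.n_bins, dtype=bool)
    mask[list(mask_bins)] = True
    values[mask] = np.nan
    return cs.ExpressionMatrix(
        grid=grid, values=values, mask=mask,
        condition_labels=[f"c{k}" for k in range(n_cond)],
    )
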