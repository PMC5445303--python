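import numpy as np
import pandas as pd
import pytest

from magefit.allele_model import PenaltyConfig
from magefit.io_formats import GenotypeTable


@pytest.fixture
def light_penalty():
    """Coarse hyperparameter search for fast unit tests on small designs."""
    return PenaltyConfig(n_alphas=20, path_eps=0.02, max_iter=2000, tol=1e-3)


@pytest.fixture
def deep_penalty():
    """Deep, tightly converged search for near-exact recovery checks."""
    return PenaltyConfig(n_alphas=40, path_eps=1e-8, max_iter=100000, tol=1e-12)


def make_genotype_table(X, doubling_times, allele_ids=None, cycles=None):
    """Assemble a GenotypeTable from a raw 0/1/NaN matrix and phenotypes."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    allele_ids = allele_ids or [f"a{j}" for j in range(p)]
    idx = pd.Index([f"cl{i:03d}" for i in range(n)], name="clone_id")
    geno = pd.DataFrame(X, index=idx, columns=allele_ids)
    meta = pd.DataFrame(
        {
            "lineage": pd.NA,
            "cycle": cycles if cycles is not None else 0,
            "doubling_time_min": np.asarray(doubling_times, dtype=float),
        },
        index=idx,
    )
    return GenotypeTable(geno, meta)


@pytest.fixture
def toy_genotype_table():
    """Five clones, two informative alleles, exact multiplicative effects."""
    X = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [1, 0]], dtype=float)
    t = 40.0 * np.exp(X @ np.array([-0.2, -0.1]))
    return make_genotype_table(X, t)
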