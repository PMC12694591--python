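import numpy as np
import pytest

from caft import CensoredTaxon, CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def micro_instance():
    """The two-point worked example: e=(0,1), delta=(1,1), X=(-0.5, 0.5)."""
    taxon = CensoredTaxon(tau=np.array([0.0, 1.0]), delta=np.array([1, 1]), taxon_id="T")
    X = np.array([[-0.5], [0.5]])
    return taxon, X


@pytest.fixture
def small_table():
    """3 taxa x 4 samples with one zero cell and unequal depths."""
    counts = np.array(
        [
            [5, 3, 2],
            [0, 6, 4],
            [7, 2, 1],
            [3, 3, 4],
        ]
    )
    return CountTable(
        counts=counts,
        sample_ids=np.array(["s1", "s2", "s3", "s4"]),
        taxon_ids=np.array(["A", "B", "C"]),
    )


def random_censored_instance(rng, n, k, censor_frac=0.3):
    """A small random censored regression instance for oracle checks."""
    X = rng.normal(size=(n, k))
    X -= X.mean(axis=0)
    beta = rng.normal(size=k)
    tau = X @ beta + rng.normal(size=n)
    cut = np.quantile(tau, 1 - censor_frac)
    delta = (tau <= cut).astype(int)
    tau = np.minimum(tau, cut)
    return CensoredTaxon(tau=tau, delta=delta), X
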