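import numpy as np
import pytest

from twinbiome.twin_model import PairedPhenotypes


def exact_moment_pairs(cov: float, n: int = 4, mean: float = 0.0, scale: float = 1.0):
    """Pairs whose sample moments (n-denominator) are exactly mean,
    variance scale**2 and correlation cov/scale**2.

    Built by pushing the four corner points (+-1, +-1) — which have
    exact mean 0, unit variance and zero covariance — through the
    Cholesky factor of the target covariance.
    """
    z = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
    z = np.tile(z, (n // 4, 1))
    target = scale**2 * np.array([[1.0, cov], [cov, 1.0]])
    chol = np.linalg.cholesky(target)
    return z @ chol.T + mean


@pytest.fixture
def exact_ae_data():
    """Per-zygosity moments: mean 0, variance 1, MZ cov 0.6, DZ cov 0.3
    — exactly consistent with an AE model (a2=0.6, e2=0.4)."""
    return PairedPhenotypes(mz=exact_moment_pairs(0.6), dz=exact_moment_pairs(0.3))


@pytest.fixture
def equal_correlation_data():
    """MZ and DZ covariances both 0.5: no additive-genetic signal, so
    the ACE maximum sits at a2=0, c2=0.5, e2=0.5."""
    return PairedPhenotypes(mz=exact_moment_pairs(0.5), dz=exact_moment_pairs(0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
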