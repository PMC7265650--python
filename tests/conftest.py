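import numpy as np
import pytest

from metaboflux.omics import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(values, feature_ids=None, sample_ids=None, log_transformed=True,
                mask=None):
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    return OmicsMatrix(
        feature_ids=feature_ids or [f"f{i}" for i in range(nf)],
        sample_ids=sample_ids or [f"s{j}" for j in range(ns)],
        values=values,
        observed_mask=mask,
        log_transformed=log_transformed,
    )


@pytest.fixture
def small_matrix():
    return make_matrix(np.arange(12, dtype=float).reshape(3, 4) + 1.0)


def random_gaussian_matrix(rng, p=5, n=100, scale_spread=True):
    """Random correlated Gaussian features x samples matrix."""
    A = rng.normal(size=(p, p))
    if scale_spread:
        A = A * rng.uniform(0.3, 1.5)
    cov = A @ A.T + np.eye(p)
    X = np.linalg.cholesky(cov) @ rng.standard_normal((p, n))
    return make_matrix(X)
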