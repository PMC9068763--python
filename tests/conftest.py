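import numpy as np
import pytest
import scipy.sparse as sp

from svargs.var_core import SparseVARModel, TimeSeries, random_sparse_stable_var, simulate


def scalar_ar(coeffs, sigma2=1.0):
    """Scalar AR model from a list of lag coefficients (lag 1, 2, ...)."""
    mats = {l + 1: sp.csr_matrix(np.array([[a]])) for l, a in enumerate(coeffs) if a != 0}
    return SparseVARModel(k=1, lags=tuple(range(1, len(coeffs) + 1)),
                          coeffs=mats, sigma=np.array([[sigma2]]))


def var_from_dense(mats, sigma=None):
    """Model from a list of dense coefficient matrices (lag 1, 2, ...)."""
    k = np.asarray(mats[0]).shape[0]
    coeffs = {l + 1: sp.csr_matrix(np.asarray(A, float))
              for l, A in enumerate(mats) if np.any(A)}
    return SparseVARModel(k=k, lags=tuple(range(1, len(mats) + 1)),
                          coeffs=coeffs,
                          sigma=np.eye(k) if sigma is None else np.asarray(sigma))


@pytest.fixture
def driver_pair_model():
    """Bivariate VAR(1): x autonomous AR(1), x drives y strongly."""
    A = np.array([[0.3, 0.0],
                  [0.9, 0.2]])
    return var_from_dense([A])


@pytest.fixture
def chain_model():
    """3-channel chain x -> y -> z (no direct x -> z link)."""
    A = np.zeros((3, 3))
    A[0, 0] = 0.3
    A[1, 0] = 0.8
    A[1, 1] = 0.2
    A[2, 1] = 0.8
    A[2, 2] = 0.2
    return var_from_dense([A])


@pytest.fixture
def white_noise_ts():
    rng = np.random.default_rng(42)
    return TimeSeries((rng.standard_normal((5, 400)),))


def strong_sampler(rng, size):
    return rng.uniform(0.4, 0.9, size) * rng.choice([-1.0, 1.0], size)


def strong_small_system(seed, k=5, order_range=(1, 3), density=0.08,
                        min_coef=0.3):
    """Random sparse stable model whose every coefficient stays strong
    after the stability rescaling (a high-SNR recovery target)."""
    for attempt in range(50):
        m = random_sparse_stable_var(k, order_range, density,
                                     coef_sampler=strong_sampler,
                                     seed=seed * 100 + attempt)
        vals = np.concatenate([np.abs(m.coeffs[l].data) for l in m.coeffs])
        if vals.min() >= min_coef:
            return m
    raise RuntimeError("could not draw a strong system")
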