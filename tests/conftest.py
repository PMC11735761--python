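import numpy as np
import pytest

from hdfit import NetArchitecture, make_fixture


@pytest.fixture(scope="session")
def fast_arch():
    """Small-budget architecture for unit tests (full 50-40-30-20 stack)."""
    return NetArchitecture(solver="lbfgs", max_iter=60)


@pytest.fixture(scope="session")
def linear_fixture():
    """Noiseless 12-sample dataset with pinned linear coefficients."""
    return make_fixture(12, 2, 3, alpha0=0.5, alpha_x=[1.0, -2.0], alpha_z=[1.5], seed=7)


class OracleModel:
    """A known regression function; ``fit`` is a no-op (used prefit)."""

    def __init__(self, beta, intercept=0.0):
        self.beta = np.asarray(beta, dtype=float)
        self.intercept = float(intercept)

    def fit(self, X, y, seed=0):
        return self

    def predict(self, X):
        return np.asarray(X) @ self.beta + self.intercept


@pytest.fixture(scope="session")
def oracle_model_cls():
    return OracleModel
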