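import numpy as np
import pytest

from covaritools.preprocessing import FeatureScaler


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def standardized(X, mode="global"):
    """Convenience: center/scale a matrix the way the estimators expect."""
    return FeatureScaler(mode=mode).fit_transform(X)


@pytest.fixture
def regression_problem(rng):
    """Standardized X (n > p) with a noisy planted linear target."""
    X = standardized(rng.standard_normal((80, 6)))
    w = rng.standard_normal((6, 2))
    Y = standardized(X @ w + 0.1 * rng.standard_normal((80, 2)), "per_column")
    return X, Y
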