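import numpy as np
import pytest

import cttkit as ck


@pytest.fixture(scope="session")
def verbal_moments():
    """Covariance matrix of the three verbal tests (packaged fixture)."""
    return ck.load_verbal_moments()


@pytest.fixture(scope="session")
def speed_moments():
    """Covariance matrix of the three speed tests (packaged fixture)."""
    return ck.load_speed_moments()


@pytest.fixture(scope="session")
def two_factor_population():
    """A 6-indicator, 2-correlated-factor population model (raw metric)."""
    lam = np.zeros((6, 2))
    lam[:3, 0] = [0.98, 1.11, 0.91]
    lam[3:, 1] = [0.67, 0.78, 0.59]
    theta = np.array([0.38, 0.42, 0.37, 0.73, 0.42, 0.67])
    phi = np.array([[1.0, 0.26], [0.26, 1.0]])
    labels = ["v1", "v2", "v3", "s1", "s2", "s3"]
    pattern = {l: ("verbal" if l.startswith("v") else "speed") for l in labels}
    return {"lam": lam, "theta": theta, "phi": phi,
            "labels": labels, "pattern": pattern}


@pytest.fixture()
def random_pd_cov():
    """Factory for random positive-definite covariance matrices."""
    def make(p, seed, positive_cov=False):
        rng = np.random.default_rng(seed)
        if positive_cov:
            lam = rng.uniform(0.4, 1.0, size=p)
            theta = rng.uniform(0.2, 0.8, size=p)
            return np.outer(lam, lam) + np.diag(theta)
        a = rng.normal(size=(p, p + 3))
        return a @ a.T / (p + 3) + 0.1 * np.eye(p)
    return make
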