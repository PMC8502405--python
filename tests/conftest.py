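import numpy as np
import pytest

from iehc.cox import SurvivalDataset
from iehc.simulate import SimConfig, simulate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_subject_data():
    """Times (1,2,3), all events: the single-covariate fit has the closed-form
    maximiser exp(beta) = sqrt(2)."""
    return SurvivalDataset(
        subject_id=np.array([1, 2, 3]),
        time=np.array([1.0, 2.0, 3.0]),
        status=np.array([1, 1, 1]),
        covariates=np.empty((3, 0)),
    )


@pytest.fixture
def null_replicate(rng):
    """One synthetic replicate under theta = tau = 0."""
    cfg = SimConfig()
    return simulate_replicate(cfg, rng), cfg


def make_survival(rng, n=150, n_cov=2, beta=None, censor=0.4):
    """Simple exponential survival data with optional covariate effects."""
    X = rng.standard_normal((n, n_cov))
    beta = np.zeros(n_cov) if beta is None else np.asarray(beta, dtype=float)
    rate = 0.05 * np.exp(X @ beta)
    T = rng.exponential(1.0 / rate)
    C = rng.exponential(1.0 / rate / (censor / (1 - censor) if censor else 1e-12))
    time = np.minimum(T, C) if censor else T
    status = (T <= C).astype(int) if censor else np.ones(n, dtype=int)
    if status.sum() == 0:
        status[0] = 1
    return SurvivalDataset(
        subject_id=np.arange(n), time=time, status=status, covariates=X
    )
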