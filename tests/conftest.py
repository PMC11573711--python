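import numpy as np
import pytest

from treelim.model import default_control_spec, prepare_predictors
from treelim.synthetic import SyntheticConfig, default_true_params, generate_drivers


@pytest.fixture(scope="session")
def spec():
    return default_control_spec()


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(nlat=20, nlon=20, seed=7)


@pytest.fixture(scope="session")
def small_drivers(small_config):
    return generate_drivers(small_config)


@pytest.fixture(scope="session")
def small_pred(small_drivers, spec):
    return prepare_predictors(small_drivers, spec)


@pytest.fixture(scope="session")
def toy_ensemble(spec, true_params):
    """A small deterministic parameter ensemble around the fixture truth.

    Built by perturbing the true vector on a fixed grid of scale factors;
    log-likelihood labels are synthetic and only used for weighting logic.
    """
    from treelim.inference import PosteriorEnsemble

    base = true_params.to_vector(spec)
    rng = np.random.default_rng(42)
    members = [base]
    for _ in range(9):
        jitter = 1.0 + 0.1 * rng.standard_normal(base.size)
        v = base * np.abs(jitter)
        # keep unit-interval parameters inside their support
        names = spec.param_names()
        for j, n in enumerate(names):
            if n in ("tc_max", "p0"):
                v[j] = min(v[j], 0.99)
        members.append(v)
    params = np.vstack(members)
    loglik = -100.0 - rng.random(params.shape[0])
    return PosteriorEnsemble(params, loglik, spec.param_names(), spec)
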