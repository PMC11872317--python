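import numpy as np
import pytest

from lcmsr.estimation import FitOptions, PanelData, fit
from lcmsr.model_spec import canonical_bivariate, compile_spec
from lcmsr.synthetic import GeneratorConfig, default_parameters, simulate_panel


@pytest.fixture(scope="session")
def canonical_spec():
    return canonical_bivariate()


@pytest.fixture(scope="session")
def canonical_ram(canonical_spec):
    return compile_spec(canonical_spec)


@pytest.fixture(scope="session")
def theta_true(canonical_ram):
    return default_parameters().theta_for(canonical_ram)


@pytest.fixture(scope="session")
def complete_panel():
    """Complete continuous two-burst panel, n = 400, at default truth."""
    cfg = GeneratorConfig(n_persons=400, retention=np.ones(14), seed=20240301)
    return simulate_panel(cfg).drop(columns="person_id")


@pytest.fixture(scope="session")
def missing_panel():
    """Panel with the default monotone attrition, n = 200."""
    cfg = GeneratorConfig(n_persons=200, seed=20240302)
    return simulate_panel(cfg).drop(columns="person_id")


@pytest.fixture(scope="session")
def canonical_fit(canonical_spec, complete_panel):
    """One converged canonical fit with sandwich SEs, reused across tests."""
    res = fit(canonical_spec, complete_panel, options=FitOptions(se="sandwich"))
    assert res.converged
    return res


def simulate_small(seed, n_persons=150, n_waves=6, **kw):
    """Cheap 6-wave (two 3-wave bursts) bivariate panel for fast unit tests."""
    half = n_waves // 2
    cfg = GeneratorConfig(
        n_persons=n_persons,
        n_waves=n_waves,
        bursts=(tuple(range(1, half + 1)), tuple(range(half + 1, n_waves + 1))),
        theta=default_parameters(n_waves),
        retention=kw.pop("retention", np.ones(n_waves)),
        seed=seed,
        **kw,
    )
    return simulate_panel(cfg).drop(columns="person_id")
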