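import numpy as np
import pytest

import guardcell as gc

#: Hand-built plausible parameter set: every kinetic term has magnitude
#: ~0.01-10 %/min at the 100-scale state; cascade timescales ~100 and ~10 min.
PLAUSIBLE = dict(
    alpha10=1.0, alpha11=5.0, alpha12=5.0, k11=5.0, k12=5.0,
    beta11=1e-4, beta12=0.5,
    alpha20=1.0, alpha21=3.0, alpha22=3.0, k21=5.0, k22=5.0,
    n1=2.0, alpha23=0.02, beta20=0.01,
    n2=2.0, beta13=0.2,
    alpha31=1.0, alpha32=1.0, k31=50.0, beta30=0.05,
    alpha40=1.0, alpha41=1.0, alpha42=0.005, beta40=0.05,
    alpha51=1.0, k51=10.0, beta50=1e-4,
)


@pytest.fixture
def params() -> gc.ModelParameters:
    return gc.ModelParameters(**PLAUSIBLE)


@pytest.fixture
def basal_params(params) -> gc.ModelParameters:
    return gc.make_basal_consistent(params)


@pytest.fixture(scope="session")
def observed() -> gc.TimeCourseDataset:
    return gc.experimental_dataset()


@pytest.fixture(scope="session")
def reference_params() -> gc.ModelParameters:
    return gc.load_reference_params()


def small_fit_config(**overrides) -> gc.FitConfig:
    """Reduced search budget for fast tests; quality checks that need the
    shipped default budget build their own FitConfig."""
    defaults = dict(n_samples=60, n_elite=8, n_rounds=2, n_refine=1,
                    refine_max_nfev=30, final_polish_max_nfev=60, seed=0)
    defaults.update(overrides)
    return gc.FitConfig(**defaults)


@pytest.fixture(scope="session")
def default_fit(observed) -> gc.FitResult:
    """The shipped default-budget fit of the primary model to the observed
    time courses (seed 0).  Session-scoped: several slow checks reuse it."""
    return gc.squeeze_and_breathe_fit(observed, gc.FitConfig(seed=0))
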