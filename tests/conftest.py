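import numpy as np
import pytest

from tumorctl import DoseSchedule, ModelParams


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def constant_dose():
    return DoseSchedule.constant()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(rng) -> ModelParams:
    """A random but physically sane parameter set for oracle sweeps."""
    return ModelParams(
        a1=rng.uniform(0.5, 2), a2=rng.uniform(0.5, 2),
        d1=rng.uniform(0.5, 2), d2=rng.uniform(0.5, 2),
        e1=rng.uniform(0, 1.5), e2=rng.uniform(0, 1.5),
        e3=rng.uniform(0, 1.5), e4=rng.uniform(0, 1.5),
        r1=rng.uniform(0, 0.5), r2=rng.uniform(0, 0.5), r3=rng.uniform(0, 0.5),
        f1=rng.uniform(0.05, 0.5), f2=rng.uniform(0.5, 2),
        alpha=rng.uniform(0, 0.5), p=rng.uniform(0, 0.1), s=rng.uniform(0.1, 1),
    )
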