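import numpy as np
import pytest

from survbit import CostModel, DetectorModel, ModelBundle, SystemModel


def make_bundle(q01=0.1, q10=0.3, p01=0.2, p11=0.8, K=0.4,
                S=(0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06)) -> ModelBundle:
    return ModelBundle(
        system=SystemModel(q01=q01, q10=q10),
        detector=DetectorModel(p01=p01, p11=p11),
        costs=CostModel(K=K, S=tuple(S)),
    )


@pytest.fixture
def default_bundle() -> ModelBundle:
    """The worked-example parameter set used throughout the unit tests."""
    return make_bundle()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
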