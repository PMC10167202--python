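import numpy as np
import pytest

from osteodyn import (ModelSpec, RemodelingParams, TumorParams, Variant,
                      default_params)


@pytest.fixture
def params() -> RemodelingParams:
    """Canonical physiological remodeling constants."""
    return default_params()[0]


@pytest.fixture
def tumor() -> TumorParams:
    return TumorParams(mu=0.005, sigma=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230315)


def spec_for(variant: Variant, **kwargs) -> ModelSpec:
    return ModelSpec(variant=variant, **kwargs)
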