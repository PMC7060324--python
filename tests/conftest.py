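import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import agropls as ag
from agropls.datamodel import VariableSpec

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return ag.default_schema()


@pytest.fixture(scope="session")
def default_dataset(schema):
    """Default synthetic study: 34 farms, 2 regions, 12 CF / 22 OF."""
    records, responses, truth = ag.generate_synthetic_farms(ag.SyntheticConfig(), seed=11)
    return records, responses, truth


@pytest.fixture(scope="session")
def linear_schema():
    """A fully continuous schema used for noiseless-limit checks, where the
    latent-to-variable mapping is affine (no thresholding or binning)."""
    return [
        VariableSpec(name=f"x{j:02d}", level="farm_description", kind="continuous",
                     valid_range=(-50.0, 50.0))
        for j in range(20)
    ]


@pytest.fixture(scope="session")
def linear_noiseless_dataset(linear_schema):
    """Noiseless latent data on the fully continuous schema: every variable is
    active for both farm types, so responses are an exact linear function of
    columns of X."""
    names = tuple(s.name for s in linear_schema)
    cfg = dataclasses.replace(
        ag.SyntheticConfig().noiseless(), active_of=names, active_cf=names
    )
    records, responses, truth = ag.generate_synthetic_farms(cfg, seed=5, schema=linear_schema)
    return records, responses, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
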