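import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spliceinfo.infomodel import InfoModel
from spliceinfo.synthetic import default_models, make_toy_gene, make_variant_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# Hand-tabulated 4-position toy weight matrix (bits); base order A C G T.
TOY_WEIGHTS = np.array(
    [
        [1.0, -0.5, 0.25, -2.0],
        [0.5, 1.5, -1.0, 0.0],
        [-0.25, 0.75, 2.0, -1.5],
        [0.0, -2.0, 1.0, 1.25],
    ]
)
# Manual dot product for window "ACGT": 1.0 + 1.5 + 2.0 + 1.25
TOY_ACGT_SCORE = 5.75
TOY_CONSENSUS = "ACGT"  # per-position argmax
TOY_MAX_SCORE = 1.0 + 1.5 + 2.0 + 1.25


@pytest.fixture(scope="session")
def toy_model() -> InfoModel:
    return InfoModel(
        name="toy",
        site_kind="donor",
        offset_start=0,
        offset_end=3,
        weights=TOY_WEIGHTS.copy(),
    )


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def splice_models(models):
    """Donor + acceptor only, the pair used for variant analysis."""
    return [models["donor"], models["acceptor"]]


@pytest.fixture(scope="session")
def gene(models):
    return make_toy_gene(models=models, seed=1)


@pytest.fixture(scope="session")
def panel(gene, models):
    return make_variant_panel(gene, models=models, seed=1)
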