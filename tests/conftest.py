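import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_model_config():
    """Desk-scale backbone used by the training-sanity checks."""
    from ntsm.model import NTSMConfig

    return NTSMConfig(
        stage_channels=(8, 16, 32),
        fhpa_encoder_stages=frozenset({2, 3}),
        fhpa_decoder_stages=frozenset({1}),
        deep_supervision_levels=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def overfit_samples():
    """Four 64×64 synthetic lesion images for capacity checks."""
    from ntsm.synthetic import SyntheticConfig, generate_sample

    cfg = SyntheticConfig(image_size=(64, 64), lesion_area_frac=(0.03, 0.12), seed=5)
    return [generate_sample(cfg, i) for i in range(4)]
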