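import numpy as np
import pytest

from metacontrol import SyntheticConfig, generate_dataset


@pytest.fixture
def five_effects():
    """Small fixed effect set with unequal variances for oracle comparisons."""
    from metacontrol.meta_core import EffectRecord

    y = [42.1, 55.3, 38.9, 61.2, 47.5]
    v = [4.0, 9.0, 2.5, 16.0, 6.0]
    return [EffectRecord(a, b, label=f"S{i}") for i, (a, b) in enumerate(zip(y, v))]


@pytest.fixture
def species_config():
    """Dog/pig dataset with one categorical effect and a follow-up slope."""
    base = SyntheticConfig()
    return SyntheticConfig(
        k_studies=165,
        true_betas={"species:pig": 21.6, "follow_up_hours": -0.03},
        tau2_true=25.0,
        level_probabilities={
            **base.level_probabilities,
            "species": {"dog": 0.6, "pig": 0.4, "sheep": 0.0},
        },
        follow_up_choices=(24.0, 72.0, 168.0, 336.0, 672.0),
        seed=11,
    )


@pytest.fixture
def small_dataset(species_config):
    return generate_dataset(species_config)
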