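import numpy as np
import pytest

from partworth import (
    AttributeSpec,
    DesignConfig,
    SyntheticConfig,
    simulate_respondents,
)


@pytest.fixture(scope="session")
def small_attributes() -> list[AttributeSpec]:
    """Four attributes with 3-4 levels each: a compact instrument."""
    return [
        AttributeSpec(1, "price", ("low", "mid", "high")),
        AttributeSpec(2, "speed", ("slow", "medium", "fast", "instant")),
        AttributeSpec(3, "support", ("none", "email", "phone")),
        AttributeSpec(4, "warranty", ("none", "1y", "2y", "lifetime")),
    ]


@pytest.fixture(scope="session")
def small_config() -> DesignConfig:
    return DesignConfig(
        n_versions=5,
        tasks_per_version=8,
        alternatives_per_task=3,
        attributes_per_task=2,
        holdout_positions=(3, 7),
        seed=11,
    )


def _small_segment_utilities(attributes, rng, spread=1.5):
    total = sum(a.n_levels for a in attributes)
    utils = rng.normal(0.0, spread, size=(2, total))
    pos = 0
    for a in attributes:
        k = a.n_levels
        block = utils[:, pos : pos + k]
        utils[:, pos : pos + k] = block - block.mean(axis=1, keepdims=True)
        pos += k
    return utils


@pytest.fixture(scope="session")
def small_synthetic(small_attributes, small_config):
    """A compact two-segment dataset with known generating truth."""
    rng = np.random.default_rng(2024)
    cfg = SyntheticConfig(
        attributes=small_attributes,
        segment_shares=np.array([0.3, 0.7]),
        segment_utilities=_small_segment_utilities(small_attributes, rng),
        design=small_config,
        n_respondents=60,
        scale=1.0,
        seed=5,
    )
    dataset, truth = simulate_respondents(cfg)
    return cfg, dataset, truth
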