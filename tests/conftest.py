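import numpy as np
import pytest

from comeal import (
    Dictionary,
    FeatureInstance,
    RandomForestLearner,
    WorldConfig,
    generate_feature_world,
)


@pytest.fixture(scope="session")
def small_world_cfg() -> WorldConfig:
    return WorldConfig(
        n_subjects=3,
        n_locations=2,
        label_set=("walk", "run", "sit", "climb"),
        sampling_hz=50.0,
        seconds_per_activity=4.0,
        channels_per_location=2,
        subject_shift_scale=0.4,
        noise_scale=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def feature_world(small_world_cfg):
    return generate_feature_world(small_world_cfg, q=6, n_per_class=40)


@pytest.fixture
def separable_pool() -> Dictionary:
    """Two far-apart Gaussian classes; trivially separable."""
    rng = np.random.default_rng(0)
    insts = []
    uid = 0
    for label, mu in (("a", -5.0), ("b", 5.0)):
        for x in rng.normal(mu, 1.0, size=(40, 4)):
            insts.append(FeatureInstance(features=x, label=label, uid=uid))
            uid += 1
    return Dictionary(insts, role="related_labeled")


@pytest.fixture
def trained_learner(separable_pool) -> RandomForestLearner:
    return RandomForestLearner(seed=0).fit(separable_pool)


def make_labeled_pool(rng, means: dict, n: int, q: int = 4, std: float = 1.0,
                      uid_start: int = 0, role: str = "related_labeled",
                      subject=None, location=None) -> Dictionary:
    """Gaussian-cluster pool with one cluster per label."""
    insts = []
    uid = uid_start
    for label, mu in means.items():
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (q,))
        for x in rng.normal(0.0, std, size=(n, q)) + mu:
            insts.append(FeatureInstance(features=x, label=label, uid=uid,
                                         subject_id=subject, location_id=location))
            uid += 1
    return Dictionary(insts, role=role)
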