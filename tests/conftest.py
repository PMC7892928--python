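"""Shared fixtures: small seeded phantoms and a tiny trained ensemble."""

from __future__ import annotations

import numpy as np
import pytest

from triseg.losses import LossConfig
from triseg.nn import NetworkConfig
from triseg.patches import AugmentConfig, SamplerConfig
from triseg.phantoms import PhantomSpec, generate_cohort, generate_subject
from triseg.training import TrainConfig, make_holdout, prepare_subjects, train_ensemble

# compact spec used wherever a full-size head is not needed
SMALL_SPEC = PhantomSpec(
    shape=(32, 32, 32),
    structure_semiaxes=(3.0, 6.0, 4.0),
    structure_offset=7.0,
    bend=2.0,
)


def small_spec(**overrides) -> PhantomSpec:
    from dataclasses import replace

    return replace(SMALL_SPEC, **overrides)


@pytest.fixture(scope="session")
def phantom_pair():
    """A default-size control phantom (image, label)."""
    return generate_subject(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def small_phantom():
    """A 32^3 control phantom (image, label) for fast tests."""
    return generate_subject(small_spec(seed=3))


@pytest.fixture(scope="session")
def small_cohort():
    """8 controls + 4 patients on the 32^3 grid."""
    return generate_cohort(8, 4, small_spec(), seed=2)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(
        epochs=2,
        patches_per_epoch=32,
        batch_size=8,
        loss=LossConfig(kind="dice"),
        sampler=SamplerConfig(patch_size=(16, 16), augment=AugmentConfig(enabled=False)),
        network=NetworkConfig(base_width=2, depth=2, output_mode="sigmoid_1ch", seed=0),
        val_patches=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ensemble(small_cohort, tiny_train_config):
    """A deliberately under-trained ensemble: cheap, but exercises the full path."""
    subjects = prepare_subjects(small_cohort)
    plan = make_holdout(small_cohort, (0.5, 0.25, 0.25), seed=1)
    models, history = train_ensemble(subjects, plan, tiny_train_config)
    return models, history, plan, subjects
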