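"""Shared fixtures: simulator building blocks and a trained contact model.

Expensive artifacts (the contact classifier, a small cohort) are session
scoped so the suite stays fast; everything is generated programmatically
from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from floorgait import evaluation, symptoms
from floorgait.synthetic import FloorModel, SensorLayout, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def floor() -> FloorModel:
    return FloorModel()


@pytest.fixture(scope="session")
def layout() -> SensorLayout:
    return SensorLayout()


@pytest.fixture(scope="session")
def contact_model(floor):
    spectra, labels = evaluation.make_contact_training_set(
        n_per_class=40, floor=floor, rng_seed=11
    )
    return symptoms.train_contact_classifier(spectra, labels, rng_seed=0)


@pytest.fixture(scope="session")
def small_cohort(layout, floor):
    return generate_cohort(
        4,
        np.full(6, 1 / 6),
        traces_per_subject_range=(2, 3),
        rng_seed=21,
        layout=layout,
        floor=floor,
        noise_sd=0.02,
        n_steps_range=(8, 10),
    )
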