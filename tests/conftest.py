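"""Shared fixtures.

Small cohorts for unit tests are cheap and function-scoped where mutation
matters; the pretraining study (2,000 patients, d=32, 2-layer encoder) is
session-scoped because several behavioral tests reuse the same fitted
encoder.
"""

from __future__ import annotations

import numpy as np
import pytest

import nextvisit as nv


@pytest.fixture(scope="session")
def tiny_config() -> nv.GeneratorConfig:
    return nv.GeneratorConfig(n_patients=80, vocab_size=60, seed=5)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config) -> list[nv.PatientRecord]:
    return nv.generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_cohort) -> nv.Vocabulary:
    return nv.build_vocabulary(tiny_cohort)


@pytest.fixture(scope="session")
def study_cohort() -> list[nv.PatientRecord]:
    """The default-condition cohort used for the behavioral analyses."""
    return nv.generate_cohort(nv.GeneratorConfig(n_patients=2000, seed=11))


@pytest.fixture(scope="session")
def study_splits(study_cohort):
    return nv.split_cohort(study_cohort, nv.SplitSpec(seed=0))


@pytest.fixture(scope="session")
def pretrained(study_cohort) -> nv.MaskedLMResults:
    """Masked-code pretraining on the study cohort (seeded, 6 epochs)."""
    model = nv.MaskedLMModel(study_cohort)
    return model.fit(epochs=6, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
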