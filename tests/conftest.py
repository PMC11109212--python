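import dataclasses

import numpy as np
import pytest

from mklfusion import RunConfig, SyntheticSpec, generate_cohort, paper_like_preset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 3-modality cohort with clear signal, for fast unit tests."""
    spec = SyntheticSpec(
        n_pos=8, n_neg=12, modality_dims=(6, 10, 4), effect_size=1.0, seed=42
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def full_cohort():
    """One cohort at the study's full feature widths (43 subjects, 4 modalities)."""
    return generate_cohort(paper_like_preset("converter_vs_nonconverter"))


@pytest.fixture
def fast_config():
    """Factory for small RunConfigs (few splits/permutations)."""

    def make(**kwargs):
        defaults = dict(n_splits=5, n_permutations=9, master_seed=0)
        defaults.update(kwargs)
        return RunConfig(**defaults)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
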