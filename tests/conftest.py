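import numpy as np
import pytest

from xynscreen import synthetic


@pytest.fixture(scope="session")
def small_family():
    """A 40-sequence family with two planted Tr+Ak clades and clean hits."""
    profile = synthetic.FamilyProfile(
        n_prokarya=30, n_eukarya=8, n_archaea=2, n_trait_clades=2,
        frac_partial=0.0, seed=11,
    )
    return synthetic.simulate_family(profile)


@pytest.fixture(scope="session")
def small_family_partial():
    """Same scale but with the default 10% sub-threshold catalytic hits."""
    profile = synthetic.FamilyProfile(
        n_prokarya=30, n_eukarya=8, n_archaea=2, n_trait_clades=2, seed=11,
    )
    return synthetic.simulate_family(profile)


@pytest.fixture(scope="session")
def identity_matrix():
    """Match +1 / mismatch -1 substitution matrix."""
    return np.eye(20) * 2 - 1
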