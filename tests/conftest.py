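import numpy as np
import pytest

from coaldelta.design import (MarkerProfile, build_focal_tree,
                              mitochondrial_profile, nuclear_profile)


@pytest.fixture(scope="session")
def focal_tree():
    """4-taxon tree at the high-discordance condition, tau1 = 1 Myr."""
    return build_focal_tree(0.025, 0.01, 1.0)


@pytest.fixture(scope="session")
def mito_profile():
    return mitochondrial_profile(0.01)


@pytest.fixture(scope="session")
def nuc_profile():
    return nuclear_profile(0.001)


@pytest.fixture(scope="session")
def plain_profile():
    """Neutral single-rate locus (r=1, h=1): theta and ages on one scale."""
    return MarkerProfile("nuclear", 1.0, 1.0, kappa=2.0, gamma_shape=1.0,
                         n_categories=4, length=1000, per_lineage_rate=0.001)
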