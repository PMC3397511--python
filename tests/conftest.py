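import numpy as np
import pytest

from gridqsar.alignment import scaffold_align
from gridqsar.chem_dataset import (
    SCAFFOLD_SMARTS,
    build_thiourea_series,
    load_packaged_activity,
)
from gridqsar.synthetic_data import SyntheticSpec, generate_set


@pytest.fixture(scope="session")
def activity():
    return load_packaged_activity()


@pytest.fixture(scope="session")
def series_graphs():
    """Packaged series with chemical graphs only (no 3D embedding)."""
    molset, act = build_thiourea_series(embed=False)
    return molset, act


@pytest.fixture(scope="session")
def aligned_series():
    """Embedded, charged and template-aligned packaged series."""
    molset, act = build_thiourea_series()
    result = scaffold_align(molset, molset["70"], SCAFFOLD_SMARTS)
    assert not result.failures
    return result, act


@pytest.fixture(scope="session")
def synth_strong():
    """Synthetic set with strong planted signal (SNR 10, n=60)."""
    spec = SyntheticSpec(n_compounds=60, n_atoms=20, n_scaffold=10,
                         sparsity=10, target_snr=10.0, seed=7)
    molset, act, truth = generate_set(spec)
    return spec, molset, act, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
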