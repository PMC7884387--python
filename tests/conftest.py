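import numpy as np
import pytest

from paleoattrib import synthetic as syn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210215)


@pytest.fixture(scope="session")
def shape_sample():
    """Two well-separated shape groups (effect 10x the landmark noise)."""
    return syn.simulate_shape_groups(
        syn.ShapeSimSpec(noise_sd=0.05, group_effects={"A": 0.5, "B": 0.5},
                         n_per_group=20, seed=20210215)
    )


@pytest.fixture(scope="session")
def coarse_phantom():
    """Bifurcated-root phantom at a coarse voxel, for fast unit tests."""
    spec = syn.PhantomSpec(
        stem_radius=4.0, stem_height=10.0, n_branches=2, branch_radius=1.8,
        branch_height=11.5, crown_radius=None, pulp_radius=1.2, voxel_size=0.1,
    )
    vol, truth = syn.simulate_tooth_phantom(spec)
    return spec, vol, truth
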