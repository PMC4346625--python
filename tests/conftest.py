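import numpy as np
import pytest

from fibremetrics.synthetic_data import (
    GeneratorConfig,
    build_ideal_fiber,
    perturb_trajectory,
)


@pytest.fixture(scope="session")
def ideal_48mer():
    """The reference construction: 48 monomers, 3.4 A spacing, -140 deg."""
    topo, frame = build_ideal_fiber(GeneratorConfig())
    return topo, frame


@pytest.fixture(scope="session")
def small_fiber():
    """A cheap 4-monomer fibre for energy bookkeeping tests."""
    cfg = GeneratorConfig(n_monomers=4, n_frames=2, stacking_sigma=0.05, seed=1)
    topo, frame = build_ideal_fiber(cfg)
    traj = perturb_trajectory(topo, cfg)
    return cfg, topo, frame, traj


@pytest.fixture(scope="session")
def jittered_fiber():
    """A disordered 8-monomer trajectory with a dihedral mixture."""
    cfg = GeneratorConfig(
        n_monomers=8,
        n_frames=10,
        stacking_sigma=0.15,
        lateral_sigma=0.3,
        dihedral_mix=(0.76, 0.19, 0.05),
        fold_factor=0.8,
        seed=42,
    )
    topo, frame = build_ideal_fiber(cfg)
    traj = perturb_trajectory(topo, cfg)
    return cfg, topo, frame, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
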