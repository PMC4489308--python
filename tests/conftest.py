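import numpy as np
import pytest

from solvaxs.formfactors import (
    apply_water_correction,
    load_default_table,
    solvent_density_correction,
)
from solvaxs.synth import SyntheticSystemSpec, generate_system_pair, generate_water_box


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def water_pair():
    """Small matched solute/water pair reused across scattering tests."""
    spec = SyntheticSystemSpec(
        solute_model="sphere-cluster", n_solute=20, solute_radius=4.0,
        box=(30.0, 30.0, 30.0), n_frames=4, seed=11,
    )
    return generate_system_pair(spec)


@pytest.fixture(scope="session")
def water_box():
    """Pure-water box, 4 frames, default density."""
    return generate_water_box((25.0, 25.0, 25.0), seed=7, n_frames=4)


@pytest.fixture(scope="session")
def corrected_table(water_box):
    s, t = water_box
    tab = apply_water_correction(load_default_table())
    return solvent_density_correction(tab, s, t, 334.0)


@pytest.fixture
def rigid_cluster():
    """20 random point atoms in a compact cloud (rigid, one frame)."""
    rng = np.random.default_rng(42)
    coords = np.empty((0, 3))
    while len(coords) < 20:
        p = rng.uniform(-1, 1, (40, 3))
        p = p[np.sum(p * p, axis=1) <= 1.0]
        coords = np.vstack([coords, p])
    return 5.0 * coords[:20]
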