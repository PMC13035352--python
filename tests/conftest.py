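import numpy as np
import pytest

from airdmd import (
    default_field_spec,
    drop_trailing_low_energy,
    generate_flow_snapshots,
    y_bifurcation_geometry,
)


@pytest.fixture(scope="session")
def geometry():
    return y_bifurcation_geometry()


@pytest.fixture(scope="session")
def field_spec(geometry):
    return default_field_spec(geometry=geometry)


@pytest.fixture(scope="session")
def deck50(field_spec):
    """Trimmed (144-frame) baseline deck at 50 L/min."""
    return drop_trailing_low_energy(generate_flow_snapshots(field_spec, 50.0))


@pytest.fixture(scope="session")
def trained_models(field_spec):
    """Full-rank models at the two bracketing training rates."""
    from airdmd import build_pair, fit

    return {
        v: fit(build_pair(drop_trailing_low_energy(generate_flow_snapshots(field_spec, v))))
        for v in (40.0, 60.0)
    }


@pytest.fixture()
def random_deck():
    """Seeded small random particle-position deck."""
    rng = np.random.default_rng(42)
    from airdmd import SnapshotSet

    return SnapshotSet(
        kind="particles", values=rng.standard_normal((3, 5, 12)), dt=0.1
    )
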