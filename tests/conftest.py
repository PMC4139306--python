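import numpy as np
import pytest

from memesp import (
    DebyeHuckelParams,
    GridSpec,
    PotentialGrid,
    SyntheticBilayerSpec,
    analytic_potential,
    generate_bilayer,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20140814)


@pytest.fixture
def small_spec():
    return GridSpec(dims=(6, 6, 6), spacing=1.0, origin=(-2.5, -2.5, -2.5))


@pytest.fixture
def grid_factory(small_spec):
    def make(values=None, seed=0, spec=None, **kw):
        spec = spec or small_spec
        if values is None:
            values = np.random.default_rng(seed).normal(size=spec.dims)
        return PotentialGrid(spec=spec, values=np.asarray(values, dtype=float), **kw)

    return make


@pytest.fixture(scope="session")
def desk_bilayer_spec():
    """Desk-scale patch: 16 lipids per leaflet, probe protruding 1 Å."""
    return SyntheticBilayerSpec(lipids_per_leaflet=16, probe_z_offset=1.0, seed=7)


@pytest.fixture(scope="session")
def desk_bilayer(desk_bilayer_spec):
    return generate_bilayer(desk_bilayer_spec)


@pytest.fixture(scope="session")
def desk_grid_spec(desk_bilayer):
    return GridSpec.centered(desk_bilayer.role_position("P1"), (25, 25, 25), 1.0)


@pytest.fixture(scope="session")
def desk_potential(desk_bilayer, desk_grid_spec):
    return analytic_potential(desk_bilayer, desk_grid_spec, DebyeHuckelParams())
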