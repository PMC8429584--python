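import warnings

import pytest

from soccf.synthetic import WorldSpec, generate_world, make_known_answer_region


@pytest.fixture(scope="session")
def registry():
    from soccf.lu_taxonomy import build_default_registry
    return build_default_registry()


@pytest.fixture(scope="session")
def world6():
    """Small synthetic world for fast unit tests."""
    return generate_world(WorldSpec(n_regions=6, n_countries=2, seed=5))


@pytest.fixture(scope="session")
def world25():
    """Study-size synthetic world (25 regions, 5 countries)."""
    return generate_world(WorldSpec(n_regions=25, n_countries=5, seed=3))


@pytest.fixture(scope="session")
def grass_region(world6):
    """A world6 region where the grassland class is feasible."""
    return next(r for r in world6.regions
                if "grassland" in r.feasible_classes)


@pytest.fixture(scope="session")
def known_answer():
    """Constant-climate oracle region with forced ASOC 100/60 and rate 0.05."""
    return make_known_answer_region(asoc_pnv=100.0, asoc_lu=60.0, k=0.05)


@pytest.fixture(autouse=True)
def _quiet_simulation_warnings():
    """Long boreal regenerations legitimately hit the horizon; keep the test
    output readable."""
    from soccf.exceptions import SimulationWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SimulationWarning)
        yield
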