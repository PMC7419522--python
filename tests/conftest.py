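import pytest

from aerotree import (AIR_BODY, Particle, TreeGeneratorParams, demo_tree,
                      generate_synthetic_tree, main_bronchus_tube)


@pytest.fixture(scope="session")
def air():
    """Dry air at body temperature."""
    return AIR_BODY


@pytest.fixture(scope="session")
def micron_particle():
    """8 µm unit-density particle (sedimentation/impaction dominated)."""
    return Particle(diameter=8e-6, density=1000.0)


@pytest.fixture(scope="session")
def fine_particle():
    """3.5 µm unit-density particle."""
    return Particle(diameter=3.5e-6, density=1000.0)


@pytest.fixture(scope="session")
def nanoparticle():
    """0.35 µm particle (diffusion dominated)."""
    return Particle(diameter=0.35e-6, density=1000.0)


@pytest.fixture(scope="session")
def bronchus_tube():
    """The printed single-tube benchmark: 6.3 cm x 1.35 cm, horizontal."""
    return main_bronchus_tube()


@pytest.fixture(scope="session")
def tree3():
    """Symmetric deterministic 3-generation tree (7 states)."""
    return demo_tree(n_generations=3)


@pytest.fixture(scope="session")
def tree6():
    """Random asymmetric 6-generation tree, fixed seed."""
    return generate_synthetic_tree(TreeGeneratorParams(n_generations=6, seed=11))
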