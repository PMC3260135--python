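import pytest

from extrafib.synthetic import SceneConfig, build_scene, project


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def default_scene(default_config):
    return build_scene(default_config)


@pytest.fixture(scope="session")
def longitudinal(default_scene):
    """Beam-direction projection: the longitudinal (x, z) view."""
    return project(default_scene, (0.0, 1.0, 0.0))


@pytest.fixture(scope="session")
def cross_section(default_scene):
    """Fibril-axis projection: the cross-section (x, y) view."""
    return project(default_scene, (0.0, 0.0, 1.0))
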