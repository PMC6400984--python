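import pytest
from hypothesis import settings

from paddysma import DEFAULT_BANDS, SceneConfig, build_library, \
    generate_endmember_library, generate_scene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture(scope="session")
def spectra():
    return generate_endmember_library(seed=1)


@pytest.fixture(scope="session")
def library(spectra, bands):
    return build_library(spectra, bands)


def small_scene_config(seed=7, **kw):
    """Study-design scene shrunk to small plot ROIs for fast tests."""
    defaults = dict(seed=seed, plot_rows=24, plot_cols=20, panel_size=10, ridge=4)
    defaults.update(kw)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(small_scene_config())


@pytest.fixture(scope="session")
def noiseless_scene():
    return generate_scene(small_scene_config(seed=2, noise_sd_dn=0.0,
                                             yield_noise_sd=0.0))
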