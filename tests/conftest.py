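import pytest

from cmcount import CountConfig, SceneSpec, load_cohort, make_slide


@pytest.fixture(scope="session")
def config():
    return CountConfig()


@pytest.fixture(scope="session")
def cohort_table():
    return load_cohort()


@pytest.fixture(scope="session")
def mixed_slide():
    """Small mixed slide with ground truth, shared across tests."""
    spec = SceneSpec(n_cmc=25, n_leuko=500, n_dual=10, n_debris=50, seed=3)
    slide, truth = make_slide(spec, n_fov=8)
    return slide, truth
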