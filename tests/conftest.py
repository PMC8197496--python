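import pytest
from hypothesis import HealthCheck, settings

from gecna import SyntheticConfig, compute_burden, generate, run_screen

settings.register_profile(
    "repro", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_dataset():
    """Reference desk-scale cohort (2,000 genes x 200 subjects)."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_burden(default_dataset):
    return compute_burden(default_dataset.cna)


@pytest.fixture(scope="session")
def default_screen(default_dataset, default_burden):
    return run_screen(default_dataset.expression, default_burden)


@pytest.fixture(scope="session")
def small_dataset():
    """A faster cohort for tests that re-run the screen several times."""
    cfg = SyntheticConfig(seed=7, n_genes=400, n_subjects=100,
                          n_amp_facilitators=8, n_del_facilitators=8,
                          n_amp_suppressors=8, n_del_suppressors=8,
                          survival_log_hrs=(0.9, 0.9, -0.9),
                          amp_base_rate=40.0, del_base_rate=40.0)
    return generate(cfg)
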