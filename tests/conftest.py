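import pytest
from hypothesis import HealthCheck, settings

from cypminer.pipeline import RunConfig, run
from cypminer.synthetic import SyntheticConfig, generate

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: scaled-down study conditions for unit tests where the brute-force DP
#: oracle must realign full sequences
SMALL_CONFIG = SyntheticConfig(
    seed=5,
    n_families=3,
    subfamilies_per_family=2,
    ref_length=(120, 160),
    n_known_subfamily=4,
    n_new_subfamily=3,
    n_new_family=2,
    n_decoy=2,
    n_incomplete=2,
    n_duplicate=2,
)


@pytest.fixture(scope="session")
def small_dataset():
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default synthetic preset."""
    out = tmp_path_factory.mktemp("run_default")
    return run(RunConfig(out_dir=str(out), synthetic=SyntheticConfig(), seed=17))


@pytest.fixture(scope="session")
def default_run_repeat(tmp_path_factory):
    """Second, independent pipeline run with the identical config and seed."""
    out = tmp_path_factory.mktemp("run_repeat")
    return run(RunConfig(out_dir=str(out), synthetic=SyntheticConfig(), seed=17))
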