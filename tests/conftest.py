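import pytest
from hypothesis import HealthCheck, settings

from cardiotox_utc import GeneratorConfig, generate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

#: single fixed seed used across the suite
SEED = 0


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config, seed=SEED)


@pytest.fixture(scope="session")
def zero_noise_cohort(default_config):
    return generate_cohort(default_config.zero_noise(), seed=SEED)


def small_config(**overrides) -> GeneratorConfig:
    """A down-scaled cohort for fast pipeline tests (12 animals, 2 hearts/dose)."""
    base = dict(
        n_baseline=12,
        group_sizes=[12, 6, 5, 4, 3, 2],
        sacrifice_schedule={0.0: 2, 8.0: 2, 12.0: 2, 16.0: 2},
        hist_n_fields=4,
        hist_field_size=64,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    from cardiotox_utc.pipeline import run_generate

    out = tmp_path_factory.mktemp("data") / "cohort"
    run_generate(small_config(), seed=SEED, out_dir=out)
    return out
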