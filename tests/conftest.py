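import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """40 strains x 100 markers on 2 chromosomes, moderate LD."""
    from eqtlbench.simulate import simulate_ri_genotypes

    return simulate_ri_genotypes(40, [(50, 100_000_000)] * 2, 5e-8, seed=7)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study bundle (100 strains, 500 markers, 60 traits)."""
    from eqtlbench.fixtures import FixtureSpec, generate_fixture

    return generate_fixture(FixtureSpec(seed=3))
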