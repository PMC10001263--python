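import pytest
from hypothesis import HealthCheck, settings

from dlahap.simulate import BreedConfig, SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_cohort():
    """The standard synthetic setting: one breed, 2000 dogs, 8 haplotypes,
    mild inbreeding (fis=0.1), a quarter of pool haplotypes 88L-structured."""
    cfg = SimConfig(
        breeds=(BreedConfig("beagle", 2000, 8, dirichlet_alpha=1.0, fis=0.1),),
        frac_88L=0.25,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def multi_breed_cohort():
    """Three small breeds sharing a haplotype pool, for breed-level stats."""
    cfg = SimConfig(
        breeds=(
            BreedConfig("akita", 40, 5, dirichlet_alpha=0.6, fis=0.1),
            BreedConfig("shiba", 35, 6, dirichlet_alpha=0.6, fis=0.0),
            BreedConfig("kishu", 30, 4, dirichlet_alpha=0.6, fis=0.2),
            BreedConfig("mongrel", 15, 8, dirichlet_alpha=1.0, fis=0.0),
        ),
        frac_88L=0.25,
        seed=7,
        shared_pool_size=12,
    )
    return simulate_cohort(cfg)
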