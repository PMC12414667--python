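import pytest
from hypothesis import HealthCheck, settings

from adh1score import phenotypes, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-stratum toy biobank: fast enough for unit tests, rich enough to
    exercise every variant class."""
    cfg = simulate.SimulationConfig(
        n_individuals=3000,
        strata=("EUR", "AFR"),
        seed=42,
        variant_classes=(
            simulate.known_gof_class(),
            simulate.VariantClassSpec(
                class_label="gof_intermediate", n_variants=5,
                carrier_count_range=(3, 60), calcium_shift_mM=(-0.08, 0.04),
                phosphate_shift_mM=(0.30, 0.05), insilico_deleterious_prob=0.7,
            ),
            simulate.VariantClassSpec(
                class_label="lof", n_variants=3, carrier_count_range=(1, 20),
                calcium_shift_mM=(0.12, 0.05), phosphate_shift_mM=(0.15, 0.05),
                insilico_deleterious_prob=0.8,
            ),
            simulate.VariantClassSpec(
                class_label="neutral", n_variants=10,
                carrier_count_range=(1, 20), insilico_deleterious_prob=0.15,
            ),
            simulate.VariantClassSpec(
                class_label="synonymous", n_variants=40,
                carrier_count_range=(1, 20), insilico_deleterious_prob=0.05,
            ),
        ),
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """Single-stratum cohort at a size where effect recovery is reliable."""
    cfg = simulate.SimulationConfig(
        n_individuals=20_000,
        strata=("EUR",),
        seed=7,
        variant_classes=simulate.default_architecture(n_synonymous=150, n_neutral=20),
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_phenotypes(medium_cohort):
    return phenotypes.build_phenotypes(medium_cohort.individuals)


@pytest.fixture(scope="session")
def small_phenotypes(small_cohort):
    return phenotypes.build_phenotypes(small_cohort.individuals)


@pytest.fixture(scope="session")
def phecode_map():
    return phenotypes.load_phecode_map()
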