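import pytest

from alirecovery import (
    ComponentId,
    GeneratorConfig,
    generate_catalog,
    generate_cohort,
    load_original_roadmap,
)


@pytest.fixture(scope="session")
def original_roadmap():
    return load_original_roadmap()


@pytest.fixture(scope="session")
def catalog(original_roadmap):
    return generate_catalog(original_roadmap, n_decoys=20, seed=11)


@pytest.fixture(scope="session")
def small_study(original_roadmap, catalog):
    """A 150-patient synthetic study shared across read-only tests."""
    config = GeneratorConfig(n_patients=150, seed=11)
    patients, biomarkers, diagnoses, chart, truth = generate_cohort(
        config, original_roadmap, catalog
    )
    return {
        "config": config,
        "patients": patients,
        "biomarkers": biomarkers,
        "diagnoses": diagnoses,
        "chart": chart,
        "truth": truth,
    }
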