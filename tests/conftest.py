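import pytest

from plastomics.synth import (
    FULL_REGIONS,
    MINI_REGIONS,
    apply_inversion,
    default_gene_catalog,
    generate_plastome,
    INV24,
    INV36,
    INV50,
)


@pytest.fixture(scope="session")
def mini_catalog():
    return default_gene_catalog("mini")


@pytest.fixture(scope="session")
def full_catalog():
    return default_gene_catalog("full")


@pytest.fixture(scope="session")
def mini_record(mini_catalog):
    return generate_plastome(mini_catalog, MINI_REGIONS, seed=11)


@pytest.fixture(scope="session")
def full_record(full_catalog):
    return generate_plastome(full_catalog, FULL_REGIONS, seed=11)


@pytest.fixture(scope="session")
def mini_inverted(mini_record):
    """Ancestral plus the three nested inversion states (mini profile)."""
    r50, e50 = apply_inversion(mini_record, INV50)
    r5036, e36 = apply_inversion(r50, INV36)
    r503624, e24 = apply_inversion(r5036, INV24)
    return {
        "ancestral": mini_record,
        "50": r50,
        "50+36": r5036,
        "50+36+24": r503624,
        "events": {"INV50": e50, "INV36": e36, "INV24": e24},
    }
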