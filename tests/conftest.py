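import pytest
from hypothesis import settings

from srnaqc import (
    LibraryConfig,
    RefConfig,
    generate_library,
    generate_reference,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ref():
    """A compact classed reference covering every annotation class."""
    return generate_reference(
        RefConfig(
            n_mirna=30,
            n_other_ncrna=10,
            n_repeat=5,
            n_coding=5,
            n_unannotated=5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def blood_ref():
    """A blood-panel-sized reference for end-to-end runs."""
    return generate_reference(
        RefConfig(
            n_mirna=300,
            n_other_ncrna=100,
            n_repeat=50,
            n_coding=30,
            n_unannotated=50,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def blood_library(blood_ref):
    """A 20k-read skewed library with its ground-truth manifest."""
    cfg = LibraryConfig(n_reads=20_000, seed=21)
    reads, manifest = generate_library(blood_ref, cfg, library_id="blood_1")
    return cfg, reads, manifest
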