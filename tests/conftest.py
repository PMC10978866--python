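import pytest

from satscreen import (
    ReferenceORF,
    enumerate_saturation_library,
    synthetic_orf,
)

TOY_NT = "ATGGCTAAATAA"  # M A K stop


@pytest.fixture(scope="session")
def toy_orf() -> ReferenceORF:
    return ReferenceORF(name="toy", nt_seq=TOY_NT)


@pytest.fixture(scope="session")
def toy_library(toy_orf):
    return enumerate_saturation_library(toy_orf)


@pytest.fixture(scope="session")
def egfr_orf() -> ReferenceORF:
    """Synthetic EGFR-scale ORF: 1210 residues with hotspot anchors planted."""
    return synthetic_orf(length_aa=1210, seed=0)


@pytest.fixture(scope="session")
def egfr_library(egfr_orf):
    return enumerate_saturation_library(egfr_orf)


@pytest.fixture(scope="session")
def small_orf() -> ReferenceORF:
    """A 30-residue ORF sized for read-level tests."""
    return synthetic_orf(length_aa=30, seed=7, anchors={})


@pytest.fixture(scope="session")
def small_library(small_orf):
    return enumerate_saturation_library(small_orf)
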