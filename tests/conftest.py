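import numpy as np
import pytest

from phosphoscan import hcm1
from phosphoscan.scheme import (
    LibrarySpec,
    PhosphositeScheme,
    Site,
    allele_table,
    uniform_library,
)

# Toy 2-site scheme used throughout: region residues 1-10, sites T3 and T7.
TOY_PROTEIN = "GNTPKDTPGF"
TOY_DNA = "GGTAACACTCCAAAGGATACTCCAGGTTTT"


@pytest.fixture
def toy_scheme() -> PhosphositeScheme:
    return PhosphositeScheme(
        sites=(Site("T3", 3, "T"), Site("T7", 7, "T")),
        region_span=(1, 10),
    )


@pytest.fixture
def toy_library(toy_scheme) -> LibrarySpec:
    return uniform_library(toy_scheme, "AE", "WW")


@pytest.fixture(scope="session")
def tad_scheme():
    return hcm1.tad_scheme()


@pytest.fixture(scope="session")
def tad_region():
    return hcm1.synthetic_tad_region()


@pytest.fixture(scope="session")
def ae_library():
    return hcm1.ae_library()


@pytest.fixture(scope="session")
def ae_alleles(ae_library, tad_region):
    """Amplicon per pool genotype (256 A/E members + WT reference)."""
    return allele_table(
        tad_region, ae_library.scheme, ae_library.pool_genotypes()
    )


@pytest.fixture(scope="session")
def ae_truth():
    """Deterministic true selection coefficients for the A/E pool."""
    lib = hcm1.ae_library()
    pool = lib.pool_genotypes()
    rng = np.random.default_rng(20240901)
    s = dict(zip(pool, rng.uniform(-0.02, 0.02, size=len(pool))))
    s[lib.reference_genotype] = 0.0
    return s
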