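import numpy as np
import pytest

from hpaudit.regions import packaged_catalogue
from hpaudit.synthetic_data import (
    BundleConfig,
    benchmark_cohort,
    toy_reference,
    write_fixture_bundle,
)


@pytest.fixture(scope="session")
def catalogue():
    return packaged_catalogue()


@pytest.fixture(scope="session")
def toy_region_6T(catalogue):
    """A 6-T homopolymer on a small synthetic contig (sequence, region)."""
    region = next(r for r in catalogue if r.region_id == "BRCA2_c.4279_4284")
    return toy_reference(region, flank=200)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Small on-disk FASTA+BAM fixture bundle (2 controls, 3 study)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(outdir, BundleConfig(reads_per_region=150, seed=11))


@pytest.fixture(scope="session")
def benchmark():
    """Cohort shaped like the audited one (injections over clean background)."""
    return benchmark_cohort(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
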