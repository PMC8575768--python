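import pytest

from snolatex import make_bundle, run_pipeline
from snolatex.synthetic_data import gen_rrna_and_sites


@pytest.fixture(scope="session")
def bundle42():
    """The default synthetic study bundle (master seed 42)."""
    return make_bundle(seed=42)


@pytest.fixture(scope="session")
def pipeline42(bundle42):
    return run_pipeline(bundle42)


@pytest.fixture(scope="session")
def small_rrnas():
    """A compact rRNA set + site catalogue for oracle-sized tests."""
    rrnas, pre, sites = gen_rrna_and_sites(
        seed=7, lengths={"18S": 400, "28S": 600, "5.8S": 120}, n_nm=40, n_psi=10
    )
    return rrnas, pre, sites
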