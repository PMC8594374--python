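"""Shared long-run simulation fixtures (session scope to amortize cost)."""
import pytest
from hypothesis import settings

import cellcycle as cc

# derandomized property tests need no example database on disk
settings.register_profile("repo", database=None)
settings.load_profile("repo")

LONG_N = 50_000


@pytest.fixture(scope="session")
def ia_lineage():
    """IA model at the reference 10%-CV conditions, 50k generations."""
    return cc.simulate_ia(cc.default_params("ia"), LONG_N, seed=101)


@pytest.fixture(scope="session")
def ia_table(ia_lineage):
    return cc.extract_observables(ia_lineage)


@pytest.fixture(scope="session")
def ida_lineage():
    return cc.simulate_ida(cc.default_params("ida"), LONG_N, seed=202)


@pytest.fixture(scope="session")
def ida_table(ida_lineage):
    return cc.extract_observables(ida_lineage)


@pytest.fixture(scope="session")
def shc_lineage():
    """sHC with fully independent draws (the sizer limit)."""
    return cc.simulate_shc(cc.default_params("shc"), LONG_N, seed=303)


@pytest.fixture(scope="session")
def shc_table(shc_lineage):
    return cc.extract_observables(shc_lineage)


@pytest.fixture(scope="session")
def rda_lineage():
    return cc.simulate_rda(cc.default_params("rda"), LONG_N, seed=404)


@pytest.fixture(scope="session")
def rda_table(rda_lineage):
    return cc.extract_observables(rda_lineage)
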