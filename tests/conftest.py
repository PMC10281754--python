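import numpy as np
import pytest

from devqtl import load_default_table
from devqtl.locus_config import AssociationSNV, CpGSite, Locus, LocusTable


@pytest.fixture(scope="session")
def table():
    """The locus panel shipped with the package."""
    return load_default_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220)


@pytest.fixture()
def mini_table():
    """A one-locus, one-CpG table for closed-loop simulation tests."""
    snv = AssociationSNV("rs0001", "1", 1000, "T", "C", 0.41)
    locus = Locus(1, [snv], ["GENE1"], [CpGSite(1, 1, 2000)])
    return LocusTable([locus])
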