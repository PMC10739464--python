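import numpy as np
import pytest

from pmhckit.anchors import BindingCore
from pmhckit.fixtures import FixtureSpec, make_benchmark_set, make_toy_pmhc2
from pmhckit.structure_io import TemplateRecord

PEP15 = "AKFVAAWTLKAAALG"


@pytest.fixture(scope="session")
def fix15():
    """Default 15-mer fixture complex (core at offset 3)."""
    return make_toy_pmhc2(FixtureSpec(peptide_seq=PEP15, core_start=3, pdb_id="T15"))


@pytest.fixture(scope="session")
def core15():
    return BindingCore(3, 15)


@pytest.fixture(scope="session")
def template15(fix15, core15):
    return TemplateRecord(fix15, core15)


@pytest.fixture(scope="session")
def benchmark_set():
    return make_benchmark_set(n_pairs=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
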