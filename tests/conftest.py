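import pytest

from pgp_lungdisp.core_io import load_assay_table, load_descriptor_table


@pytest.fixture(scope="session")
def table1():
    return load_descriptor_table("table1")


@pytest.fixture(scope="session")
def table2():
    return load_assay_table("table2", "iam_mlv")


@pytest.fixture(scope="session")
def table3():
    return load_assay_table("table3", "ussing_papp")
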