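import pysam
import pytest

from splicequant.gene_models import load_fixture


@pytest.fixture(scope="session")
def toy_model():
    return load_fixture("toy_maptlike")


@pytest.fixture(scope="session")
def pig_model():
    return load_fixture("pig_mapt")


@pytest.fixture(scope="session")
def human_model():
    return load_fixture("human_mapt")


@pytest.fixture()
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": "chr12", "LN": 20_000_000}, {"SN": "chrT", "LN": 2000}],
        }
    )
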