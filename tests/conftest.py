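import pytest

from kturnfold import synthetic_data
from kturnfold.kturn_model import Nucleotide, PairId, parse_kturn


@pytest.fixture
def kt7():
    return synthetic_data.kt7_template()


@pytest.fixture
def u4_like():
    return synthetic_data.u4_like_template()


@pytest.fixture
def toy_kturn():
    # spec-style toy: GAA loop at indices 3-5, 1b=G at index 6
    return parse_kturn("GGCGAAGAACC", "GGUGAUCGCC", loop_start=3, loop_length=3,
                       name="toy")


@pytest.fixture
def octahedron_pdb(tmp_path):
    path = tmp_path / "octahedron.pdb"
    synthetic_data.write_fixture_structure("ideal_octahedron", path)
    return path


@pytest.fixture
def two_ion_pdb(tmp_path):
    path = tmp_path / "two_ion.pdb"
    synthetic_data.write_fixture_structure("two_ion_kt7_like", path)
    return path


def make_pair(b: str, n: str) -> PairId:
    return PairId(Nucleotide(b), Nucleotide(n), 3)
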