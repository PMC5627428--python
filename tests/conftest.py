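import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.util as `util`

from famkit import SpeciesMap, example_species_tree, parse_newick


@pytest.fixture
def smap():
    """Delimiter map matching the simulator's g<k>_<species> labels."""
    return SpeciesMap.from_delimiter("_")


@pytest.fixture
def species8():
    """The stock dated 8-species tree (A..H, ultrametric, height 1)."""
    return example_species_tree()


@pytest.fixture
def textbook_dup_tree():
    """((g1_X,g2_Y),(g3_X,g4_Y)): one ancient duplication over 2 species."""
    return parse_newick("((g1_X:1,g2_Y:1):1,(g3_X:1,g4_Y:1):1);")
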