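import numpy as np
import pytest

from assemblyscope.community_data import AsvTable, Phylogeny, TaxonomyTable

QUARTET_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick(QUARTET_NEWICK)


@pytest.fixture
def small_table() -> AsvTable:
    return AsvTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[5, 0], [3, 2], [0, 4]]),
    )


@pytest.fixture
def random_table() -> AsvTable:
    rng = np.random.default_rng(42)
    counts = rng.poisson(8, size=(10, 6)).astype(float)
    counts[0, :] += 1  # keep every sample non-empty
    return AsvTable(
        [f"t{i}" for i in range(10)],
        [f"s{j}" for j in range(6)],
        counts,
    )


@pytest.fixture
def simple_taxonomy() -> TaxonomyTable:
    return TaxonomyTable.from_lineage_strings(
        {
            "t1": "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__GenA;s__sp1",
            "t2": "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__GenA;s__sp2",
            "t3": "k__Bacteria;p__P2;c__C2;o__O2;f__F2;g__GenB;s__",
        }
    )
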