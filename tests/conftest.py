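import numpy as np
import pytest
from hypothesis import settings

from kmerlca.taxonomy import TaxonomyTree

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")


@pytest.fixture
def small_tree():
    """1 -> {2, 3}; 2 -> {4, 5}.  Node 2 is a genus with species 4, 5."""
    return TaxonomyTree(
        {
            1: (1, "no rank", "root"),
            2: (1, "genus", "G"),
            3: (1, "genus", "H"),
            4: (2, "species", "G.a"),
            5: (2, "species", "G.b"),
        }
    )


@pytest.fixture
def seven_rank_tree():
    """Two complete seven-rank lineages sharing a family.

    root(1) > kingdom(2) > phylum(3) > class(4) > order(5) > family(6)
    > genus(7) > species(8), plus a sibling genus(9) > species(10) and a
    second phylum lineage 11..16.
    """
    return TaxonomyTree(
        {
            1: (1, "no rank", "root"),
            2: (1, "kingdom", "K"),
            3: (2, "phylum", "P1"),
            4: (3, "class", "C1"),
            5: (4, "order", "O1"),
            6: (5, "family", "F1"),
            7: (6, "genus", "G1"),
            8: (7, "species", "S1"),
            9: (6, "genus", "G2"),
            10: (9, "species", "S2"),
            11: (2, "phylum", "P2"),
            12: (11, "class", "C2"),
            13: (12, "order", "O2"),
            14: (13, "family", "F2"),
            15: (14, "genus", "G3"),
            16: (15, "species", "S3"),
        }
    )


def random_tree(rng: np.random.Generator, n: int) -> TaxonomyTree:
    """Random rooted tree with taxids 1..n, root 1, arbitrary rank labels."""
    ranks = ["no rank", "species", "genus", "family", "order", "class", "phylum"]
    nodes = {1: (1, "no rank", "root")}
    for t in range(2, n + 1):
        parent = int(rng.integers(1, t))
        nodes[t] = (parent, ranks[int(rng.integers(len(ranks)))], f"n{t}")
    return TaxonomyTree(nodes)
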