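import numpy as np
import pytest

from phytodisparity import (
    CharacterMatrix,
    Phylogeny,
    SyntheticScenario,
    generate,
)
from phytodisparity.matrix_io import INAPPLICABLE, MISSING


@pytest.fixture
def five_tip_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:2):1.5,(C:0.7,(D:1.2,E:0.3):0.4):1);")


@pytest.fixture
def balanced_dated_tree() -> Phylogeny:
    """Ultrametric 8-tip tree, root age 8, splits at 8, 4 and 2 Ma."""
    sub = "(({a}:2,{b}:2):2,({c}:2,{d}:2):2):4"
    nwk = f"({sub.format(a='A', b='B', c='C', d='D')},{sub.format(a='E', b='F', c='G', d='H')});"
    return Phylogeny.from_newick(nwk)


@pytest.fixture
def small_matrix() -> CharacterMatrix:
    cells = np.array(
        [
            [0, 1, 2],
            [1, MISSING, 2],
            [0, INAPPLICABLE, 1],
            [1, 1, MISSING],
        ],
        dtype=np.int16,
    )
    return CharacterMatrix(
        ["ta", "tb", "tc", "td"],
        ["c1", "c2", "c3"],
        cells,
        partitions={"veg": ["c1", "c2"], "rep": ["c2", "c3"]},
    )


def random_tree(rng: np.random.Generator, n_tips: int, max_blen: float = 2.0) -> Phylogeny:
    """Random binary topology with uniform branch lengths, for oracles."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.uniform_pure_birth_tree(
        taxon_namespace=taxa, birth_rate=1.0, rng=__import__("random").Random(int(rng.integers(2**31)))
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, max_blen))
    return Phylogeny.from_dendropy(tree)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scenario synthetic study shared across tests."""
    return generate(SyntheticScenario(), seed=20260925)
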