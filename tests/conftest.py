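import numpy as np
import pytest

from tfcat.sequence_io import ProteinRecord, Proteome
from tfcat.synthetic import DEFAULT_TOY_FAMILIES, toy_registry, write_family_map
from tfcat.tree_annotation import GeneTree, TreeNode


@pytest.fixture
def registry():
    return toy_registry()


@pytest.fixture
def family_map_path(tmp_path):
    path = tmp_path / "family_map.tsv"
    write_family_map(DEFAULT_TOY_FAMILIES, path)
    return path


@pytest.fixture
def toy_hmm_db(tmp_path):
    from tfcat.synthetic import build_toy_hmm_db

    path = tmp_path / "toy_dbd.hmm"
    build_toy_hmm_db(path, seed=0)
    return path


def make_proteome(*specs):
    """Build a Proteome from (seq_id, gene_id, sequence) triples."""
    records = [
        ProteinRecord(
            seq_id=s,
            sequence=seq,
            gene_id=g,
            description=f"gene={g}" if g else "",
            attributes={"gene": g} if g else {},
        )
        for s, g, seq in specs
    ]
    return Proteome(species="test", records=records)


def random_tree(n_leaves: int, rng: np.random.Generator, prefix: str = "L") -> GeneTree:
    """Random binary tree with exponential branch lengths (test instance generator)."""
    subtrees = [
        TreeNode(label=f"{prefix}{i}", length=float(rng.exponential(1.0)) + 1e-3)
        for i in range(n_leaves)
    ]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False).tolist())
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        node = TreeNode(length=float(rng.exponential(1.0)) + 1e-3, children=[a, b])
        a.parent = node
        b.parent = node
        subtrees.append(node)
    root = subtrees[0]
    root.length = None
    return GeneTree(root)


def naive_patristic(tree: GeneTree, leaf_a: str, leaf_b: str) -> float:
    """Independent oracle: sum branch lengths along root paths up to the LCA."""
    def path_to_root(leaf):
        node, out = tree.leaf(leaf), []
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]  # root first

    pa, pb = path_to_root(leaf_a), path_to_root(leaf_b)
    k = 0
    while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
        k += 1
    return sum(n.length for n in pa[k:]) + sum(n.length for n in pb[k:])
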