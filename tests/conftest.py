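import io

import numpy as np
import pytest
from skbio import TreeNode

from ansbr.data_model import ASVTable


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


@pytest.fixture
def four_leaf_tree() -> TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1); — the classic balanced quartet."""
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_table() -> ASVTable:
    counts = np.array(
        [
            [10, 5, 0, 1],
            [3, 0, 7, 2],
            [4, 4, 4, 4],
        ]
    )
    return ASVTable(["s1", "s2", "s3"], ["A", "B", "C", "D"], counts)


def random_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random topology with exponential branch lengths (independent of the
    package's own generator: different join order and length scale)."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        idx = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(idx[1]))
        a = nodes.pop(int(idx[0]))
        la, lb = rng.exponential(1.0, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return tree_from_newick(nodes[0] + ";")


def brute_force_unifrac(tree: TreeNode, set_a, set_b) -> float:
    """Independent unweighted UniFrac oracle: enumerate every branch and its
    descendant tip set directly from the tree."""
    set_a, set_b = set(set_a), set(set_b)
    shared_total = 0.0
    unique_total = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        tips = {t.name for t in node.tips()} or {node.name}
        in_a = bool(tips & set_a)
        in_b = bool(tips & set_b)
        if in_a or in_b:
            shared_total += length
            if in_a != in_b:
                unique_total += length
    return unique_total / shared_total if shared_total else 0.0
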