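import numpy as np
import pytest

from saltrait.phylo import TreeIndex, tree_from_newick
from saltrait.synthetic import generate_yule_tree


@pytest.fixture
def quartet():
    """Balanced 4-tip tree ((A,B),(C,D)) with unit branch lengths."""
    return TreeIndex.from_dendropy(tree_from_newick("((A,B),(C,D));"))


@pytest.fixture
def balanced16():
    """Perfectly balanced 16-tip tree, tips T01..T16."""
    tips = [f"T{i:02d}" for i in range(1, 17)]

    def nest(labels):
        if len(labels) == 1:
            return labels[0]
        mid = len(labels) // 2
        return f"({nest(labels[:mid])},{nest(labels[mid:])})"

    return TreeIndex.from_dendropy(tree_from_newick(nest(tips) + ";"))


def random_index(n_tips: int, seed: int) -> TreeIndex:
    return TreeIndex.from_dendropy(generate_yule_tree(n_tips, seed))


def random_states(index: TreeIndex, seed: int, k: int | None = None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    states = np.zeros(index.n_tips, dtype=np.int64)
    if k is None:
        k = int(rng.integers(1, index.n_tips))
    states[rng.choice(index.n_tips, size=k, replace=False)] = 1
    return states
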