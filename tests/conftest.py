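import dendropy
import numpy as np
import pytest

from seasonbrain import SimulationConfig, generate_study_dataset


@pytest.fixture
def three_tip_tree() -> dendropy.Tree:
    """((A:1,B:1):1,C:2); — shared paths computable by hand."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def cherry_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic study at the default design (30 sp, 171 individuals)."""
    return generate_study_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def analysis_inputs(default_dataset):
    traits, climate, tree, daily = default_dataset
    return traits, climate, tree, daily


def brute_force_vcv(tree: dendropy.Tree, order: list[str]) -> np.ndarray:
    """Independent covariance oracle: root-to-MRCA path sums per tip pair."""
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    def ancestors(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    def depth(node):
        total = 0.0
        while node.parent_node is not None:
            total += node.edge.length
            node = node.parent_node
        return total

    n = len(order)
    V = np.zeros((n, n))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i == j:
                V[i, j] = depth(leaves[a])
            else:
                anc = set(id(x) for x in ancestors(leaves[a]))
                node = leaves[b]
                while id(node) not in anc:
                    node = node.parent_node
                V[i, j] = depth(node)
    return V
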