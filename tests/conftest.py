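import pytest
from hypothesis import settings

import ethnophylo as ep

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

THREE_TIP = "((A:1,B:1):1,C:2);"
CATERPILLAR5 = "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
STAR3 = "(A:1,B:1,C:1);"


@pytest.fixture
def three_tip_tree():
    return ep.parse_newick(THREE_TIP)


@pytest.fixture
def three_tip_dmat(three_tip_tree):
    return three_tip_tree.patristic_matrix()


@pytest.fixture
def caterpillar5():
    return ep.parse_newick(CATERPILLAR5)


@pytest.fixture
def caterpillar5_dmat(caterpillar5):
    return caterpillar5.patristic_matrix()


@pytest.fixture
def toy_records():
    return [
        ep.UseRecord("T1", "Skin", region="Tropical Africa"),
        ep.UseRecord("T2", "Skin", region="Tropical Africa"),
        ep.UseRecord("T1", "Pain", region="Indomalaya", condition="headache"),
        ep.UseRecord("T3", "Infections/Fever", region="Neotropics", condition="malaria"),
    ]


def naive_patristic(tree, a, b):
    """Independent oracle: path length via explicit parent-pointer walks."""
    node_a = tree._leaf_by_label[a]
    node_b = tree._leaf_by_label[b]

    def path_to_root(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa = path_to_root(node_a)
    pb = path_to_root(node_b)
    ancestors_a = {id(n): i for i, n in enumerate(pa)}
    for n in pb:
        if id(n) in ancestors_a:
            lca = n
            break
    dist = 0.0
    for node in (node_a, node_b):
        while node is not lca:
            dist += node.edge.length
            node = node.parent_node
    return dist
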