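import numpy as np
import pytest

from mzosim.trees import Phylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def two_tip_tree():
    # ((A:5, B:5)) as arrays: root, two pendant edges of length 5
    return Phylogeny([-1, 0, 0], [0.0, 5.0, 5.0], [None, "A", "B"])


@pytest.fixture
def balanced_tree_10():
    """Ultrametric 10-tip balanced-ish tree built by repeated pairing."""
    return random_ultrametric_tree(10, seed=5)


def random_ultrametric_tree(n_tips: int, seed: int, prefix: str = "s") -> Phylogeny:
    """Random coalescent-style ultrametric tree (test helper, not the
    simulator under test)."""
    rng = np.random.default_rng(seed)
    nodes = [
        {"children": [], "height": 0.0, "label": f"{prefix}{i+1}"} for i in range(n_tips)
    ]
    active = list(range(n_tips))
    h = 0.0
    while len(active) > 1:
        h += rng.exponential(1.0)
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        nodes.append({"children": [a, b], "height": h, "label": None})
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [len(nodes) - 1]
    children = [nd["children"] for nd in nodes]
    lengths = [0.0] * len(nodes)
    parent_height = {}
    root = len(nodes) - 1
    for idx in range(len(nodes) - 1, -1, -1):
        for c in nodes[idx]["children"]:
            lengths[c] = nodes[idx]["height"] - nodes[c]["height"]
    labels = [nd["label"] for nd in nodes]
    return Phylogeny.from_children(children, lengths, labels, root=root)


def brute_force_path_distance(tree: Phylogeny, i: int, j: int) -> float:
    """Path-walk oracle: climb to root from both tips, sum unshared edges."""
    anc_i = {}
    node, d = i, 0.0
    while node != -1:
        anc_i[node] = d
        d += tree.edge_length[node]
        node = tree.parent[node]
    node, d = j, 0.0
    while node not in anc_i:
        d += tree.edge_length[node]
        node = tree.parent[node]
    return d + anc_i[node]
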