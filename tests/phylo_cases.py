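"""Shared phylogeny test constructions: random additive trees and
well-separated sequence clusters."""

import numpy as np
from skbio import DistanceMatrix, TreeNode

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_additive_tree(n, rng):
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.5, 2.0)))
             for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.5, 2.0)))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


def tree_to_dm(tree):
    labels = [t.name for t in tree.tips()]
    td = tree.tip_tip_distances(endpoints=labels)
    arr = np.array([[0.0 if a == b else td[a, b] for b in labels]
                    for a in labels])
    return DistanceMatrix(arr, ids=labels)


def clustered_sequences(seed=1):
    """Two well-separated 4-taxon clusters: within-cluster distance ~0.01,
    between ~0.5."""
    rng = np.random.default_rng(seed)

    def mutate(base, n):
        s = list(base)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = AA[rng.integers(20)]
        return "".join(s)

    base_a = "".join(rng.choice(AA, 100))
    base_b = mutate(base_a, 55)   # ~0.5 between clusters
    return [("a1", base_a), ("a2", mutate(base_a, 1)),
            ("b1", base_b), ("b2", mutate(base_b, 1))]
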