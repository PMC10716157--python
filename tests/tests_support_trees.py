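"""Shared helpers for phylogenetic-diversity tests: random rooted trees
and a brute-force Faith's PD oracle."""

from skbio import TreeNode


def random_tree(rng, n_tips):
    """Random rooted bifurcating tree with uniform random branch lengths."""
    nodes = [TreeNode(name=f"T{i}", length=round(float(rng.uniform(0.1, 2.0)), 3))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(children=[a, b], length=round(float(rng.uniform(0.1, 2.0)), 3))
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    root = nodes[0]
    root.length = None
    return root


def brute_force_pd(tree, observed):
    """Sum branch lengths over the union of observed-tip-to-root paths."""
    edges = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in observed:
            continue
        node = tip
        while node.parent is not None:
            key = id(node)
            if key not in edges:
                edges.add(key)
                total += node.length or 0.0
            node = node.parent
    return total
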