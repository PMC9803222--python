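"""Shared oracles and random-instance generators for the tree tests."""

import itertools

import numpy as np
from skbio import DistanceMatrix, TreeNode

from paralogon_kit import phylo as ph


def _sp_tree():
    return TreeNode.read(iter(["((A:1,B:1)AB:1,(C:1,D:1)CD:1)Root;"]))


def _random_tree(n_taxa, rng, ultrametric=False):
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    heights = {id(n): 0.0 for n in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode()
        if ultrametric:
            h = max(heights[id(a)], heights[id(b)]) + rng.uniform(0.2, 1.0)
            a.length = h - heights[id(a)]
            b.length = h - heights[id(b)]
            heights[id(parent)] = h
        else:
            a.length = float(rng.uniform(0.1, 1.0))
            b.length = float(rng.uniform(0.1, 1.0))
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _additive_matrix(tree):
    tips = [t.name for t in tree.tips()]
    n = len(tips)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.find(tips[i]).distance(tree.find(tips[j]))
    return DistanceMatrix(d, tips)



def _oracle_min_cost(gene_tree, sp_tree, species_of=ph.default_species_of):
    """Exhaustive reconciliation: minimum duplication+loss cost over all
    valid mappings of internal gene nodes to species nodes."""
    sp_nodes = {n.name: n for n in sp_tree.traverse(include_self=True)}
    ancestors = {}
    for name, node in sp_nodes.items():
        chain, cur = [], node
        while cur is not None:
            chain.append(cur.name)
            cur = cur.parent
        ancestors[name] = chain  # self first, root last

    def lca(a, b):
        ca = ancestors[a]
        for x in ancestors[b]:
            if x in ca:
                return x
        raise AssertionError

    def dist(top, bottom):
        return ancestors[bottom].index(top)

    internals = [v for v in gene_tree.postorder(include_self=True) if not v.is_tip()]
    leaf_map = {v: species_of(v.name) for v in gene_tree.tips()}

    best = [np.inf]

    def cost_of(assignment):
        dups = losses = 0
        for v in internals:
            m = assignment[v]
            cms = [
                assignment[c] if not c.is_tip() else leaf_map[c] for c in v.children
            ]
            low = cms[0]
            for other in cms[1:]:
                low = lca(low, other)
            is_dup = m != low or any(cm == m for cm in cms)
            if is_dup:
                dups += 1
            for cm in cms:
                d = dist(m, cm)
                losses += d if is_dup else max(0, d - 1)
        return dups, losses

    def rec(i, assignment):
        if i == len(internals):
            d, l = cost_of(assignment)
            best[0] = min(best[0], d + l)
            return
        v = internals[i]
        cms = [assignment[c] if not c.is_tip() else leaf_map[c] for c in v.children]
        low = cms[0]
        for other in cms[1:]:
            low = lca(low, other)
        for choice in ancestors[low]:
            assignment[v] = choice
            rec(i + 1, assignment)
        del assignment[v]

    # children processed before parents (postorder list order)
    rec(0, {})
    return best[0]


def _random_gene_tree(rng, species, max_leaves=8):
    n = int(rng.integers(2, max_leaves + 1))
    leaves = [f"{rng.choice(species)}|g{i}" for i in range(n)]
    nodes = [TreeNode(name=name, length=1.0) for name in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=1.0)
        parent.extend([nodes[i], nodes[j]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


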