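"""Brute-force reference implementations used to validate the fast paths.

These deliberately work on the dendropy tree object with naive traversals,
independent of the array engine in :mod:`nconserve.conservation`.
"""

from __future__ import annotations

from math import comb

import numpy as np


def brute_consensus_clades(tree, trait: dict, threshold: float = 0.9):
    """Enumerate every internal node, test the strict fraction rule, keep
    nodes with no qualifying ancestor; uncovered trait-positive tips become
    singletons at half the nearest-neighbour patristic distance.

    Returns (set of (frozenset of tips, depth), tau_d).
    """
    t = tree.dendropy_tree
    leaf_sets = {}
    for nd in t.postorder_node_iter():
        if not nd.child_nodes():
            leaf_sets[id(nd)] = frozenset([nd.taxon.label])
        else:
            s = frozenset()
            for c in nd.child_nodes():
                s = s | leaf_sets[id(c)]
            leaf_sets[id(nd)] = s

    def qualifies(nd):
        if not nd.child_nodes():
            return False
        tips = leaf_sets[id(nd)]
        frac = sum(bool(trait[x]) for x in tips) / len(tips)
        return frac > threshold

    def mean_depth(nd):
        total, count = 0.0, 0
        for leaf in nd.leaf_iter():
            d, cur = 0.0, leaf
            while cur is not nd:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            total += d
            count += 1
        return total / count

    clades = set()
    covered = set()
    for nd in t.preorder_node_iter():
        if not qualifies(nd):
            continue
        anc, blocked = nd.parent_node, False
        while anc is not None:
            if qualifies(anc):
                blocked = True
                break
            anc = anc.parent_node
        if blocked:
            continue
        clades.add((leaf_sets[id(nd)], round(mean_depth(nd), 10)))
        covered |= leaf_sets[id(nd)]

    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    for tax in taxa:
        if bool(trait[tax.label]) and tax.label not in covered:
            nn = min(pdm.patristic_distance(tax, o) for o in taxa if o is not tax)
            clades.add((frozenset([tax.label]), round(nn / 2.0, 10)))
    depths = [d for _, d in clades]
    tau = float(np.mean(depths)) if depths else float("nan")
    return clades, tau


def brute_d_sum(tree, trait: dict) -> float:
    """Explicit recursive post-order accumulation of sister differences."""
    t = tree.dendropy_tree

    def value(nd):
        if not nd.child_nodes():
            return float(trait[nd.taxon.label]), 0.0
        (v1, s1), (v2, s2) = (value(c) for c in nd.child_nodes())
        return (v1 + v2) / 2.0, s1 + s2 + abs(v1 - v2)

    return value(t.seed_node)[1]


def brute_two_tailed(k: int, n: int) -> float:
    """Count the 2^n equiprobable outcomes in each tail and double the
    smaller one (exact integer arithmetic)."""
    lo = sum(comb(n, i) for i in range(0, k + 1))
    hi = sum(comb(n, i) for i in range(k, n + 1))
    return min(1.0, 2.0 * min(lo, hi) / 2**n)
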