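"""Independent oracles used by the test suite.

Each oracle re-derives an expected value by brute force (exhaustive
enumeration or closed form) without touching the implementation path it
checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from phylotestis.njtree import PhyloTree, _Node
from phylotestis.trees import SpeciesTree


def dollo_bruteforce(
    pattern: Mapping[str, bool], tree: SpeciesTree
) -> Tuple[Optional[str], int]:
    """Minimal-cost single-gain placement by exhaustive search.

    For every branch whose subtree covers all present leaves, the minimal
    loss set is characterised directly: losses are the nodes inside the
    gain subtree whose own subtree holds no present leaf while their
    parent's subtree holds at least one.  Returns (gain branch, cost).
    """
    present = {leaf for leaf, state in pattern.items() if state}
    if not present:
        return None, 0
    best: Optional[Tuple[str, int]] = None
    for label in tree.branch_labels:
        gain_node = tree.node(label)
        if not present <= set(tree.subtree_leaves(label)):
            continue
        # strict descendants of the gain node
        descendants = []
        stack = list(gain_node.children)
        while stack:
            node = stack.pop()
            descendants.append(node)
            stack.extend(node.children)
        losses = 0
        for node in descendants:
            node_leaves = set(tree.subtree_leaves(node.label))
            parent_leaves = set(tree.subtree_leaves(node.parent.label))
            if not (node_leaves & present) and (parent_leaves & present):
                losses += 1
        cost = 1 + losses
        if best is None or cost < best[1]:
            best = (label, cost)
    assert best is not None
    return best


def random_additive_tree(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    """Random unrooted binary tree with strictly positive branch lengths."""
    nodes = [_Node(f"t{i:02d}", float(rng.uniform(0.5, 2.0))) for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = _Node(None, float(rng.uniform(0.5, 2.0)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = _Node()
    root.children = nodes
    return PhyloTree(root)


def fisher_enumeration(table) -> Tuple[float, float]:
    """Fisher p-values by direct factorial enumeration (math.comb only)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    total = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == total:
        return 1.0, 1.0
    denom = math.comb(total, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p_two = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    p_one = sum(p for k, p in probs.items() if k >= a)
    return min(p_one, 1.0), min(p_two, 1.0)


def fitch_min_changes(codons_per_leaf: Mapping[str, str], tree: SpeciesTree) -> int:
    """Minimum substitutions for one codon column by exhaustive labelling.

    With unit costs an optimal labelling only uses states observed at the
    leaves, so enumerating observed-state assignments over internal nodes
    is exact.
    """
    states = sorted(set(codons_per_leaf.values()))
    internal = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for assign in itertools.product(states, repeat=len(internal)):
        labels = {n.label: s for n, s in zip(internal, assign)}
        labels.update(codons_per_leaf)
        changes = sum(
            1
            for node in tree.preorder()
            if node.parent is not None
            and labels[node.label] != labels[node.parent.label]
        )
        best = min(best, changes)
    return int(best)


def ng_pathway_enumeration(codon_a: str, codon_b: str, code: Dict[str, str], stops) -> Tuple[float, float]:
    """Re-derive pathway-averaged (nd, sd) from scratch for hand checks."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []
    for order in itertools.permutations(diff):
        cur = codon_a
        path = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            path.append(code[cur] == code[nxt])
            cur = nxt
        if ok:
            results.append(path)
    assert results, "no stop-free pathway"
    sd = sum(sum(p) for p in results) / len(results)
    return len(diff) - sd, sd
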