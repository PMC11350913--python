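"""Dollo-parsimony mapping of presence/absence patterns onto the species tree.

Expression presence/absence evolves under a single-origin rule: a gene's
testis expression is gained exactly once and may be lost independently any
number of times afterwards (re-gain is disallowed).  Under that rule the
gain branch is forced — it is the branch above the MRCA of the present
leaves — and the minimal loss set is the set of maximal subtrees below the
gain that contain no present leaf.  Optimality of this placement is exercised
against an exhaustive gain-placement search in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import pandas as pd

from .expression import PresenceAbsenceMatrix
from .trees import SpeciesTree, TreeNode

__all__ = ["GainLossEntry", "dollo_map", "aggregate_gainloss", "implied_states"]


@dataclass(frozen=True)
class GainLossEntry:
    """Dollo reconstruction for one gene."""

    gain_branch: Optional[str]  # None for genes absent everywhere
    loss_branches: FrozenSet[str]
    cost: int  # 1 + number of losses; 0 when never expressed


def dollo_map(pattern: Mapping[str, bool], tree: SpeciesTree) -> GainLossEntry:
    """Infer the single gain branch and minimal loss branches for a pattern.

    ``pattern`` maps every leaf name to its presence state.  The implied
    leaf states of the reconstruction are re-derived and asserted to equal
    the observation on every call.
    """
    leaves = set(tree.leaf_names)
    if set(pattern) != leaves:
        missing = leaves - set(pattern)
        extra = set(pattern) - leaves
        raise ValueError(
            f"pattern/leaf mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    present = [name for name in tree.leaf_names if pattern[name]]
    if not present:
        return GainLossEntry(None, frozenset(), 0)

    gain = tree.mrca(present)
    losses: List[str] = []

    def descend(node: TreeNode) -> None:
        for child in node.children:
            if any(pattern[leaf] for leaf in tree.subtree_leaves(child.label)):
                descend(child)
            else:
                losses.append(child.label)

    descend(gain)
    entry = GainLossEntry(gain.label, frozenset(losses), 1 + len(losses))
    assert implied_states(entry, tree) == {k: bool(v) for k, v in pattern.items()}
    return entry


def implied_states(entry: GainLossEntry, tree: SpeciesTree) -> Dict[str, bool]:
    """Leaf states implied by a gain/loss assignment (present iff the leaf
    descends from the gain branch and from no loss branch)."""
    states = {leaf: False for leaf in tree.leaf_names}
    if entry.gain_branch is None:
        return states
    lost = set()
    for loss in entry.loss_branches:
        lost.update(tree.subtree_leaves(loss))
    for leaf in tree.subtree_leaves(entry.gain_branch):
        states[leaf] = leaf not in lost
    return states


def aggregate_gainloss(
    pam: PresenceAbsenceMatrix, tree: SpeciesTree
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, List[str]]]]:
    """Per-branch gain/loss counts and the gene lists behind them.

    Returns a table indexed by branch label with ``gains`` and ``losses``
    columns, and a mapping branch -> {"gains": [...], "losses": [...]}.
    Genes absent in every species are reported under the ``never_expressed``
    pseudo-branch (gains column only).
    """
    if set(pam.species) != set(tree.leaf_names):
        raise ValueError(
            "species mismatch between matrix and tree: "
            f"matrix {sorted(pam.species)} vs tree {sorted(tree.leaf_names)}"
        )
    branches = tree.branch_labels + ["never_expressed"]
    counts = pd.DataFrame(0, index=branches, columns=["gains", "losses"])
    gene_lists: Dict[str, Dict[str, List[str]]] = {
        b: {"gains": [], "losses": []} for b in branches
    }
    for gene in pam.gene_ids:
        entry = dollo_map(pam.pattern(gene), tree)
        if entry.gain_branch is None:
            counts.loc["never_expressed", "gains"] += 1
            gene_lists["never_expressed"]["gains"].append(gene)
            continue
        counts.loc[entry.gain_branch, "gains"] += 1
        gene_lists[entry.gain_branch]["gains"].append(gene)
        for loss in entry.loss_branches:
            counts.loc[loss, "losses"] += 1
            gene_lists[loss]["losses"].append(gene)
    return counts, gene_lists
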