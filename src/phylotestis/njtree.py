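"""Distance matrices, neighbor-joining, bootstrap and clade rate statistics.

Trees are built from raw pairwise difference counts (not model-corrected
distances) by the Saitou–Nei neighbor-joining algorithm, so branch lengths
stay in "number of differences" units and can feed count-based exact tests.
Negative NJ branch lengths are clamped to zero with the deficit transferred
to the sister branch created at the same join (Kuhner–Felsenstein), which
preserves total tree length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Literal, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io import Alignment

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "CladeStats",
    "RateComparison",
    "count_differences",
    "complete_deletion_mask",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "clade_branch_stats",
    "rate_asymmetry_test",
    "compare_clade_rates",
]


# ---------------------------------------------------------------------------
# distances


def complete_deletion_mask(aln: Alignment) -> List[int]:
    """0-based columns where no sequence has a gap."""
    seqs = list(aln.seqs.values())
    return [
        i for i in range(aln.n_columns) if all(s[i] != "-" for s in seqs)
    ]


def count_differences(
    a: str,
    b: str,
    deletion: Literal["complete", "pairwise"] = "pairwise",
    mask: Optional[Sequence[int]] = None,
) -> int:
    """Number of differing comparable columns between two aligned sequences.

    With pairwise deletion a column is comparable when both sequences are
    non-gap; with complete deletion the caller supplies the gap-free column
    ``mask`` of the whole alignment.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if deletion == "complete":
        if mask is None:
            raise ValueError("complete deletion requires a column mask")
        cols = mask
    else:
        cols = [i for i in range(len(a)) if a[i] != "-" and b[i] != "-"]
    return sum(1 for i in cols if a[i] != b[i])


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    units: str = "differences"
    deletion: str = "complete"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        self.matrix = m

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6g"
        )


def _encode(aln: Alignment) -> np.ndarray:
    """Sequences as a (n_seqs, n_columns) byte matrix, alignment name order."""
    return np.frombuffer(
        "".join(aln.seqs[n] for n in aln.names).encode(), dtype="S1"
    ).reshape(len(aln.names), aln.n_columns)


_GAP = np.bytes_(b"-")


def _distances_from_array(
    arr: np.ndarray, deletion: str
) -> np.ndarray:
    n = arr.shape[0]
    m = np.zeros((n, n))
    nongap = arr != _GAP
    if deletion == "complete":
        cols = nongap.all(axis=0)
        sub = arr[:, cols]
        for i in range(n):
            diff = sub != sub[i]
            m[i] = diff.sum(axis=1)
    else:
        for i in range(n):
            comparable = nongap & nongap[i]
            m[i] = ((arr != arr[i]) & comparable).sum(axis=1)
    np.fill_diagonal(m, 0)
    return m


def distance_matrix(
    aln: Alignment, deletion: Literal["complete", "pairwise"] = "complete"
) -> DistanceMatrix:
    """All pairwise difference counts for an alignment (>= 3 sequences)."""
    names = aln.names
    if len(names) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    m = _distances_from_array(_encode(aln), deletion)
    return DistanceMatrix(names, m, deletion=deletion)


# ---------------------------------------------------------------------------
# trees


class _Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: List["_Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree from NJ; the stored root is the final trifurcation."""

    root: _Node
    support: Dict[FrozenSet[str], float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> List[str]:
        out: List[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out.append(node.name)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    @property
    def total_length(self) -> float:
        total = 0.0

        def walk(node: _Node) -> None:
            nonlocal total
            total += node.length
            for c in node.children:
                walk(c)

        walk(self.root)
        return total

    def splits(self) -> FrozenSet[FrozenSet[str]]:
        """Nontrivial bipartitions, each encoded as the leaf side that
        excludes the lexicographically smallest leaf."""
        leaves = frozenset(self.leaf_names)
        ref = min(leaves)
        out = set()

        def walk(node: _Node) -> FrozenSet[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(leaves) - 2:
                side = below if ref not in below else leaves - below
                out.add(side)
            return below

        walk(self.root)
        return frozenset(out)

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaves (additivity oracle)."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        m = np.zeros((n, n))

        def walk(node: _Node) -> Dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            per_child = []
            for c in node.children:
                dists = {k: v + c.length for k, v in walk(c).items()}
                per_child.append(dists)
            for a in range(len(per_child)):
                for b in range(a + 1, len(per_child)):
                    for la, da in per_child[a].items():
                        for lb, db in per_child[b].items():
                            m[index[la], index[lb]] = m[index[lb], index[la]] = da + db
            merged: Dict[str, float] = {}
            for dists in per_child:
                merged.update(dists)
            return merged

        walk(self.root)
        return DistanceMatrix(names, m, units="path length")

    def newick(self, include_support: bool = False) -> str:
        def fmt(node: _Node, top: bool = False) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and not top:
                    below = frozenset(_leaves_below(node))
                    leaves = frozenset(self.leaf_names)
                    ref = min(leaves)
                    side = below if ref not in below else leaves - below
                    if side in self.support:
                        body += f"{self.support[side]:g}"
            return body if top else f"{body}:{node.length:g}"

        return fmt(self.root, top=True) + ";"


def _leaves_below(node: _Node) -> List[str]:
    if node.is_leaf:
        return [node.name]
    out: List[str] = []
    for c in node.children:
        out.extend(_leaves_below(c))
    return out


def _transfer_clamp(la: float, lb: float) -> Tuple[float, float]:
    """Zero-clamp a negative length, moving the deficit to its sister."""
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei NJ; exact on additive matrices.

    Ties in the Q-criterion are broken toward the lowest index pair in input
    order, so the result is deterministic.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: List[_Node] = [_Node(name) for name in d.labels]
    m = d.matrix.copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = m.sum(axis=1)
        q = (k - 2) * m - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        qvals = q[iu]
        # lowest index pair in input order among exact minima (deterministic)
        best_flat = int(np.flatnonzero(qvals == qvals.min())[0])
        i, j = int(iu[0][best_flat]), int(iu[1][best_flat])
        li = 0.5 * m[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = m[i, j] - li
        li, lj = _transfer_clamp(li, lj)
        parent = _Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (m[i, :] + m[j, :] - m[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        m2 = np.zeros((k - 1, k - 1))
        m2[:-1, :-1] = m[np.ix_(keep, keep)]
        m2[-1, :-1] = m2[:-1, -1] = new_row[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        m = m2

    # final trifurcation: closed-form lengths for the three remaining nodes
    la = 0.5 * (m[0, 1] + m[0, 2] - m[1, 2])
    lb = 0.5 * (m[0, 1] + m[1, 2] - m[0, 2])
    lc = 0.5 * (m[0, 2] + m[1, 2] - m[0, 1])
    lens = [la, lb, lc]
    for idx in range(3):
        if lens[idx] < 0:
            other = max(range(3), key=lambda x: lens[x])
            lens[other] += lens[idx]
            lens[idx] = 0.0
    root = _Node()
    for node, length in zip(nodes, lens):
        node.length = max(length, 0.0)
        root.children.append(node)
    return PhyloTree(root)


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 0,
    deletion: Literal["complete", "pairwise"] = "complete",
) -> PhyloTree:
    """NJ tree with per-bipartition bootstrap support (percent of
    column-resampled replicates containing the split)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(distance_matrix(aln, deletion=deletion))
    target = tree.splits()
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    n_cols = aln.n_columns
    names = aln.names
    arr = _encode(aln)
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        m = _distances_from_array(arr[:, cols], deletion)
        rep_splits = neighbor_joining(DistanceMatrix(names, m)).splits()
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    tree.support = {s: 100.0 * c / replicates for s, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# clade statistics and the rate-asymmetry exact test


@dataclass
class CladeStats:
    clade: FrozenSet[str]
    lengths: List[float]  # all branches within the clade, stem excluded
    stem_length: float
    mean: float
    sd: float  # population sd


def _rooted_dendropy(tree: PhyloTree, outgroup: str):
    dt = dendropy.Tree.get(
        data=tree.newick(), schema="newick", preserve_underscores=True
    )
    og = dt.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not found in tree")
    dt.is_rooted = True
    dt.to_outgroup_position(og, update_bipartitions=True)
    return dt


def clade_branch_stats(
    tree: PhyloTree, clade: Sequence[str], outgroup: str = "chicken"
) -> CladeStats:
    """Branch lengths within a clade after outgroup rooting.

    The clade must be monophyletic in the rooted tree; the stem branch is
    reported separately and excluded from the mean/sd.
    """
    clade_set = frozenset(clade)
    dt = _rooted_dendropy(tree, outgroup)
    taxa = [dt.taxon_namespace.get_taxon(name) for name in clade]
    if any(t is None for t in taxa):
        missing = [n for n, t in zip(clade, taxa) if t is None]
        raise ValueError(f"clade leaves not in tree: {missing}")
    mrca = dt.mrca(taxa=taxa)
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if under != clade_set:
        raise ValueError(
            f"clade not monophyletic: subtree also contains {sorted(under - clade_set)}"
        )
    lengths = [
        float(nd.edge.length or 0.0)
        for nd in mrca.preorder_iter()
        if nd is not mrca
    ]
    stem = float(mrca.edge.length or 0.0)
    return CladeStats(
        clade=clade_set,
        lengths=lengths,
        stem_length=stem,
        mean=float(np.mean(lengths)),
        sd=float(np.std(lengths)),
    )


@dataclass
class RateComparison:
    table: List[List[int]]
    p_one_sided: float
    p_two_sided: float
    stats_a: Optional[CladeStats] = None
    stats_b: Optional[CladeStats] = None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def rate_asymmetry_test(
    k_a: float,
    k_b: float,
    sites: int,
    branches_a: int = 1,
    branches_b: int = 1,
) -> RateComparison:
    """Exact test of unequal substitution rates between two branch sets.

    Substitution counts are contrasted against unchanged site-passages:
    the 2x2 table is ``[[k_a, branches_a*sites - k_a],
    [k_b, branches_b*sites - k_b]]``, tested with Fisher's exact test
    (one-sided direction: set A faster).
    """
    from .codonsel import fisher_exact

    if k_a < 0 or k_b < 0:
        raise ValueError("substitution counts must be non-negative")
    ka, kb = _round_half_up(k_a), _round_half_up(k_b)
    cap_a, cap_b = branches_a * sites, branches_b * sites
    if ka > cap_a or kb > cap_b:
        raise ValueError("substitution count exceeds branch capacity")
    table = [[ka, cap_a - ka], [kb, cap_b - kb]]
    res = fisher_exact(table)
    return RateComparison(table, res.p_one_sided, res.p_two_sided)


def compare_clade_rates(
    tree: PhyloTree,
    clade_a: Sequence[str],
    clade_b: Sequence[str],
    sites: int,
    outgroup: str = "chicken",
    include_stem: bool = False,
) -> RateComparison:
    """Fisher rate contrast between two clades of a difference-count tree.

    Sums branch lengths (in difference-count units) within each clade,
    optionally including the stem branch, and delegates to
    :func:`rate_asymmetry_test` with the branch counts as capacity.
    """
    sa = clade_branch_stats(tree, clade_a, outgroup)
    sb = clade_branch_stats(tree, clade_b, outgroup)
    ka, na = sum(sa.lengths), len(sa.lengths)
    kb, nb = sum(sb.lengths), len(sb.lengths)
    if include_stem:
        ka, na = ka + sa.stem_length, na + 1
        kb, nb = kb + sb.stem_length, nb + 1
    res = rate_asymmetry_test(ka, kb, sites, na, nb)
    res.stats_a, res.stats_b = sa, sb
    return res
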