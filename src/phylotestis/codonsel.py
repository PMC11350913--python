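"""Codon-level selection analysis: Nei–Gojobori counting, Fitch ancestors,
stem and pairwise dN/dS, and Fisher exact tests on substitution counts.

The dN/dS (omega) estimator is Nei–Gojobori (1986) counting: each codon
position contributes a synonymous-site fraction computed over its non-stop
single-nucleotide neighbours, and differences between codons are classified
by averaging over all minimal mutational pathways that avoid stop codons.
Raw proportions pN = Nd/N and pS = Sd/S give omega by default; a
Jukes–Cantor multiple-hit correction is flag-selectable.  Stem-lineage
omega compares Fitch-reconstructed ancestral sequences at the two ends of a
clade's stem branch, using only codon columns where both ends resolve
unambiguously.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, List, Literal, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import hypergeom

from .io import Alignment
from .trees import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "NGCounts",
    "FisherResult",
    "AncestralAssignment",
    "StopPathwayError",
    "ng_site_counts",
    "ng_differences",
    "pair_dnds",
    "fitch_ancestral",
    "stem_dnds",
    "fisher_exact",
    "selection_asymmetry_test",
    "clade_pairwise_dnds",
]

BASES = "TCAG"
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class StopPathwayError(ValueError):
    """Raised when every minimal pathway between two codons crosses a stop."""


@lru_cache(maxsize=None)
def _code(table_id: int = 1) -> Tuple[Dict[str, str], FrozenSet[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def is_stop(codon: str, table_id: int = 1) -> bool:
    return codon in _code(table_id)[1]


def translate(codon: str, table_id: int = 1) -> str:
    forward, stops = _code(table_id)
    if codon in stops:
        return "*"
    return forward[codon]


def _check_codon(codon: str, table_id: int) -> None:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not a gap-free codon: {codon!r}")
    if is_stop(codon, table_id):
        raise ValueError(f"stop codon {codon!r} not allowed here")


@lru_cache(maxsize=None)
def ng_site_counts(codon: str, table_id: int = 1) -> Tuple[float, float]:
    """Nonsynonymous and synonymous site counts (n, s) for one codon.

    At each of the three positions the synonymous fraction is the share of
    synonymous changes among the non-stop single-nucleotide neighbours at
    that position; stops are excluded from the denominator.  Always
    n + s = 3.
    """
    _check_codon(codon, table_id)
    aa = translate(codon, table_id)
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(neighbor, table_id):
                continue
            valid += 1
            if translate(neighbor, table_id) == aa:
                syn += 1
        if valid:
            s_sites += syn / valid
    return 3.0 - s_sites, s_sites


@lru_cache(maxsize=None)
def ng_differences(
    codon_a: str, codon_b: str, table_id: int = 1
) -> Tuple[float, float]:
    """Nonsynonymous and synonymous difference counts (nd, sd) between two
    codons, averaged over all minimal stop-free mutational pathways."""
    _check_codon(codon_a, table_id)
    _check_codon(codon_b, table_id)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt, table_id):
                blocked = True
                break
            steps.append(
                translate(current, table_id) == translate(nxt, table_id)
            )
            current = nxt
        if not blocked:
            pathways.append(steps)
    if not pathways:
        raise StopPathwayError(
            f"no stop-free pathway between {codon_a} and {codon_b}"
        )
    sd = float(np.mean([sum(steps) for steps in pathways]))
    nd = len(diff_positions) - sd
    return nd, sd


@dataclass
class NGCounts:
    """Nei–Gojobori site/difference counts and derived quantities."""

    N: float = 0.0
    S: float = 0.0
    Nd: float = 0.0
    Sd: float = 0.0
    codons_retained: int = 0
    codons_skipped: Dict[str, int] = field(default_factory=dict)
    correction: Literal["none", "jc"] = "none"

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")

    @staticmethod
    def _jc(p: float) -> float:
        if math.isnan(p):
            return p
        if p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    @property
    def dN(self) -> float:
        return self._jc(self.pN)

    @property
    def dS(self) -> float:
        return self._jc(self.pS)

    @property
    def omega_defined(self) -> bool:
        num, den = (self.dN, self.dS) if self.correction == "jc" else (self.pN, self.pS)
        return not math.isnan(num) and not math.isnan(den) and den > 0

    @property
    def omega(self) -> Optional[float]:
        """dN/dS under the configured correction; None when the synonymous
        denominator is zero or undefined (never reported as infinity)."""
        if not self.omega_defined:
            return None
        if self.correction == "jc":
            return self.dN / self.dS
        return self.pN / self.pS


def pair_dnds(
    a: str,
    b: str,
    table_id: int = 1,
    correction: Literal["none", "jc"] = "none",
) -> NGCounts:
    """Nei–Gojobori dN/dS between two aligned coding sequences.

    Codon columns containing a gap, an ambiguous base, a stop in either
    sequence, or joined only by stop-crossing pathways are excluded and
    counted in ``codons_skipped``.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("sequence length not divisible by 3")
    counts = NGCounts(correction=correction)
    skipped = {"gap": 0, "ambiguous": 0, "stop": 0, "no_pathway": 0}
    for i in range(len(a) // 3):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if "-" in ca or "-" in cb:
            skipped["gap"] += 1
            continue
        if set(ca + cb) - set("ACGT"):
            skipped["ambiguous"] += 1
            continue
        if is_stop(ca, table_id) or is_stop(cb, table_id):
            skipped["stop"] += 1
            continue
        try:
            nd, sd = ng_differences(ca, cb, table_id)
        except StopPathwayError:
            skipped["no_pathway"] += 1
            continue
        na, sa = ng_site_counts(ca, table_id)
        nb, sb = ng_site_counts(cb, table_id)
        counts.N += (na + nb) / 2
        counts.S += (sa + sb) / 2
        counts.Nd += nd
        counts.Sd += sd
        counts.codons_retained += 1
    counts.codons_skipped = {k: v for k, v in skipped.items() if v}
    if sum(skipped.values()):
        logger.debug("pair_dnds skipped codons: %s", counts.codons_skipped)
    return counts


# ---------------------------------------------------------------------------
# Fitch ancestral codon reconstruction


@dataclass
class AncestralAssignment:
    """Per-node codon state sets (Fitch) and resolved states.

    ``resolved[label][i]`` is the codon at column-triplet ``i`` for the
    named node, or None when the state is ambiguous/missing.  Leaf rows
    echo the observed codons.  ``n_changes`` is the parsimony change count
    (number of union operations in the bottom-up pass, summed over columns).
    """

    state_sets: Dict[str, List[Optional[FrozenSet[str]]]]
    resolved: Dict[str, List[Optional[str]]]
    n_changes: int

    def sequence(self, label: str, missing: str = "---") -> str:
        return "".join(c if c else missing for c in self.resolved[label])


def fitch_ancestral(aln: Alignment, tree: SpeciesTree) -> AncestralAssignment:
    """Fitch small parsimony over whole-codon states on a fixed tree.

    Bottom-up: a node's set is the intersection of its children's sets when
    non-empty, else their union (each union costs one change).  Top-down: a
    node resolves to its parent's resolved state when that state is in its
    set, to its single element when the set is a singleton, and is marked
    ambiguous otherwise.  Leaf codons containing gaps or ambiguity codes
    are treated as missing.
    """
    leaves = set(tree.leaf_names)
    if not leaves <= set(aln.names):
        raise ValueError(
            f"alignment missing tree leaves: {sorted(leaves - set(aln.names))}"
        )
    n_codons = aln.n_columns // 3
    if aln.n_columns % 3:
        raise ValueError("alignment length not divisible by 3")
    state_sets: Dict[str, List[Optional[FrozenSet[str]]]] = {
        node.label: [None] * n_codons for node in tree.preorder()
    }
    resolved: Dict[str, List[Optional[str]]] = {
        node.label: [None] * n_codons for node in tree.preorder()
    }
    n_changes = 0

    for i in range(n_codons):
        # bottom-up
        for node in tree.postorder():
            if node.is_leaf:
                codon = aln.codon(node.label, i)
                ok = "-" not in codon and not (set(codon) - set("ACGT"))
                state_sets[node.label][i] = frozenset([codon]) if ok else None
            else:
                child_sets = [
                    state_sets[c.label][i]
                    for c in node.children
                    if state_sets[c.label][i] is not None
                ]
                if not child_sets:
                    state_sets[node.label][i] = None
                else:
                    inter = frozenset.intersection(*child_sets)
                    if inter:
                        state_sets[node.label][i] = inter
                    else:
                        state_sets[node.label][i] = frozenset.union(*child_sets)
                        n_changes += len(child_sets) - 1
        # top-down
        for node in tree.preorder():
            sset = state_sets[node.label][i]
            if sset is None:
                continue
            if node.is_leaf:
                resolved[node.label][i] = next(iter(sset))
                continue
            parent_state = (
                resolved[node.parent.label][i] if node.parent is not None else None
            )
            if parent_state is not None and parent_state in sset:
                resolved[node.label][i] = parent_state
            elif len(sset) == 1:
                resolved[node.label][i] = next(iter(sset))
            # else ambiguous: stays None

    return AncestralAssignment(state_sets, resolved, n_changes)


def stem_dnds(
    aln: Alignment,
    tree: SpeciesTree,
    clade: str,
    table_id: int = 1,
    correction: Literal["none", "jc"] = "none",
) -> NGCounts:
    """dN/dS along a clade's stem branch.

    Compares the Fitch-resolved ancestral sequence at the clade's MRCA with
    the resolved sequence at its parent node, over codon columns where both
    ends are unambiguous; ambiguous columns are excluded and counted.
    """
    if clade in tree:
        stem_label = clade
    elif f"{clade}_stem" in tree:
        stem_label = f"{clade}_stem"
    else:
        raise KeyError(f"clade {clade!r} not found in tree")
    node = tree.node(stem_label)
    if node.parent is None:
        raise ValueError(f"{stem_label!r} is the root; it has no stem branch")
    anc = fitch_ancestral(aln, tree)
    child_states = anc.resolved[node.label]
    parent_states = anc.resolved[node.parent.label]
    kept = [
        i
        for i in range(len(child_states))
        if child_states[i] is not None and parent_states[i] is not None
    ]
    seq_child = "".join(child_states[i] for i in kept)
    seq_parent = "".join(parent_states[i] for i in kept)
    counts = pair_dnds(seq_parent, seq_child, table_id=table_id, correction=correction)
    n_ambiguous = len(child_states) - len(kept)
    if n_ambiguous:
        counts.codons_skipped["ambiguous_ancestor"] = n_ambiguous
    return counts


# ---------------------------------------------------------------------------
# Fisher exact test on 2x2 count tables


@dataclass
class FisherResult:
    table: List[List[int]]
    p_one_sided: float
    p_two_sided: float
    no_information: bool = False


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Fisher's exact test by full hypergeometric enumeration.

    Two-sided p sums the probabilities of all margin-fixed tables no more
    probable than the observed one; the one-sided direction is enrichment
    of the top-left cell (row A rate greater).
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("table entries must be non-negative")
    if any(x != int(x) for x in cells):
        raise ValueError("table entries must be integers")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    total = r1 + r2
    no_info = total == 0
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == total:
        return FisherResult([[a, b], [c, d]], 1.0, 1.0, no_information=no_info)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, r1, c1)
    p_obs = pmf[a - lo]
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p_one = float(pmf[support >= a].sum())

    def snap(p: float) -> float:
        # float summation residue: a full-support sum is exactly 1
        if p > 1.0 - 1e-9:
            return 1.0
        return p

    return FisherResult([[a, b], [c, d]], snap(p_one), snap(p_two))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def selection_asymmetry_test(counts_a: NGCounts, counts_b: NGCounts) -> FisherResult:
    """Fisher contrast of nonsynonymous vs synonymous difference counts
    between two branches/pairs (e.g. the two stem lineages).

    Fractional Nd/Sd are rounded half-up to integers; rounding deltas are
    logged.  An all-zero table yields p = 1 with ``no_information`` set.
    """
    cells = [counts_a.Nd, counts_a.Sd, counts_b.Nd, counts_b.Sd]
    rounded = [_round_half_up(x) for x in cells]
    deltas = [r - x for r, x in zip(rounded, cells)]
    if any(abs(d) > 1e-9 for d in deltas):
        logger.debug("selection_asymmetry_test rounding deltas: %s", deltas)
    table = [[rounded[0], rounded[1]], [rounded[2], rounded[3]]]
    return fisher_exact(table)


@dataclass
class CladePairwiseResult:
    """Within-clade pairwise dN/dS summary."""

    pairs: Dict[Tuple[str, str], NGCounts]
    mean_counts: NGCounts
    mean_omega: Optional[float]


def clade_pairwise_dnds(
    aln: Alignment,
    clade: Sequence[str],
    table_id: int = 1,
    correction: Literal["none", "jc"] = "none",
) -> CladePairwiseResult:
    """Mean Nei–Gojobori counts and omega over all within-clade pairs."""
    members = [m for m in clade]
    if len(members) < 2:
        raise ValueError("clade must have at least 2 members")
    pairs: Dict[Tuple[str, str], NGCounts] = {}
    for x, y in itertools.combinations(members, 2):
        pairs[(x, y)] = pair_dnds(
            aln.seqs[x], aln.seqs[y], table_id=table_id, correction=correction
        )
    results = list(pairs.values())
    mean_counts = NGCounts(
        N=float(np.mean([r.N for r in results])),
        S=float(np.mean([r.S for r in results])),
        Nd=float(np.mean([r.Nd for r in results])),
        Sd=float(np.mean([r.Sd for r in results])),
        codons_retained=int(np.mean([r.codons_retained for r in results])),
        correction=correction,
    )
    omegas = [r.omega for r in results if r.omega is not None]
    mean_omega = float(np.mean(omegas)) if omegas else None
    return CladePairwiseResult(pairs, mean_counts, mean_omega)
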