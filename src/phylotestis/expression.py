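"""Expression matrix loading, RPKM binarization and clade classification.

The comparative design scores a gene as testis-expressed in a species when
its RPKM is at or above a cutoff (1.0 by default) and silent below it; the
resulting presence/absence profile across the 10 species is what evolves on
the tree.  A gene is "clade-specific" when it is present in every member of
the clade and in no species outside it (strict reading); a relaxed reading
(at least one member of each immediate subclade, none outside) and a
Dollo-mapping-based labelling are also available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PresenceAbsenceMatrix",
    "CladeDefinition",
    "default_clades",
    "read_expression_table",
    "binarize",
    "universal_set",
    "classify_pattern",
]


@dataclass
class ExpressionMatrix:
    """Gene x species RPKM values (non-negative, no missing cells)."""

    values: pd.DataFrame  # index = gene ids, columns = species
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix has no species columns")
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            bad = np.argwhere(~(np.isfinite(arr) & (arr >= 0)))
            g, s = bad[0]
            raise ValueError(
                "invalid RPKM for gene "
                f"{self.values.index[g]!r}, species {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def species(self) -> List[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


@dataclass
class PresenceAbsenceMatrix:
    """Binary testis-expression states at a recorded RPKM cutoff."""

    states: pd.DataFrame  # boolean, same shape as the source matrix
    cutoff: float = 1.0

    @property
    def gene_ids(self) -> List[str]:
        return list(self.states.index)

    @property
    def species(self) -> List[str]:
        return list(self.states.columns)

    def pattern(self, gene_id: str) -> Dict[str, bool]:
        return {s: bool(v) for s, v in self.states.loc[gene_id].items()}


@dataclass(frozen=True)
class CladeDefinition:
    name: str
    members: frozenset

    @classmethod
    def make(cls, name: str, members: Sequence[str]) -> "CladeDefinition":
        return cls(name, frozenset(members))


def default_clades(tree: Optional[SpeciesTree] = None) -> List[CladeDefinition]:
    """Mammalia/Theria/Eutheria/Marsupialia read off the species tree."""
    tree = tree or SpeciesTree.default()
    return [
        CladeDefinition.make(name, tree.clade_leaves(name))
        for name in ("Mammalia", "Theria", "Eutheria", "Marsupialia")
    ]


def read_expression_table(path) -> ExpressionMatrix:
    """Load a gene x species RPKM table from TSV.

    The first column holds gene ids; remaining columns are species.  Genes
    with any missing or unparseable cell are dropped (counted in
    ``n_dropped`` and logged).  A negative value is an error, not a drop —
    it indicates a corrupt table rather than a missing measurement.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no species columns")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    parsed = raw.apply(pd.to_numeric, errors="coerce")
    neg = parsed < 0
    if neg.to_numpy().any():
        gene = parsed.index[neg.any(axis=1)][0]
        species = parsed.columns[neg.loc[gene]][0]
        raise ValueError(
            f"{path}: negative RPKM for gene {gene!r}, species {species!r}"
        )
    complete = parsed.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "dropped %d gene(s) with missing/unparseable cells: %s",
            n_dropped,
            parsed.index[~complete].tolist(),
        )
    return ExpressionMatrix(parsed.loc[complete].astype(float), n_dropped=n_dropped)


def binarize(matrix: ExpressionMatrix, cutoff: float = 1.0) -> PresenceAbsenceMatrix:
    """Presence iff RPKM >= cutoff (the boundary value itself is present)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return PresenceAbsenceMatrix(matrix.values >= cutoff, cutoff=cutoff)


def universal_set(pam: PresenceAbsenceMatrix) -> List[str]:
    """Genes present in every species, in input order."""
    mask = pam.states.all(axis=1)
    return list(pam.states.index[mask])


def _check_nested(clades: Sequence[CladeDefinition]) -> None:
    for i, a in enumerate(clades):
        for b in clades[i + 1 :]:
            inter = a.members & b.members
            if inter and not (a.members <= b.members or b.members <= a.members):
                raise ValueError(
                    f"clades {a.name!r} and {b.name!r} overlap without nesting"
                )


def classify_pattern(
    pam: PresenceAbsenceMatrix,
    clades: Optional[Sequence[CladeDefinition]] = None,
    mode: Literal["strict", "relaxed", "dollo"] = "strict",
    tree: Optional[SpeciesTree] = None,
) -> pd.Series:
    """Per-gene expression-category labels.

    strict
        ``<clade>-specific`` iff present in all clade members and no
        non-member.  When clades nest, the most inclusive match wins.
    relaxed
        present in at least one member of each immediate subclade of the
        clade (on the species tree) and in no non-member.
    dollo
        label each gene by its Dollo-inferred gain branch (delegates to
        :mod:`phylotestis.gainloss`).

    Genes present everywhere are labelled ``universal``; genes present
    nowhere ``never_expressed``; anything else unmatched is ``other``.
    """
    species = set(pam.species)
    if mode == "dollo":
        from .gainloss import dollo_map

        tree = tree or SpeciesTree.default()
        labels = {}
        for gene in pam.gene_ids:
            entry = dollo_map(pam.pattern(gene), tree)
            labels[gene] = entry.gain_branch or "never_expressed"
        return pd.Series(labels, name="category")

    clades = list(clades) if clades is not None else default_clades(tree)
    for clade in clades:
        extra = clade.members - species
        if extra:
            raise ValueError(f"clade {clade.name!r} has unknown species {sorted(extra)}")
    _check_nested(clades)
    ordered = sorted(clades, key=lambda c: len(c.members), reverse=True)

    if mode == "relaxed":
        tree = tree or SpeciesTree.default()
        subclades = {
            c.name: [
                frozenset(tree.subtree_leaves(ch.label))
                for ch in tree.mrca(c.members).children
            ]
            for c in ordered
        }

    labels = {}
    for gene in pam.gene_ids:
        row = pam.states.loc[gene]
        present = frozenset(row.index[row])
        if not present:
            labels[gene] = "never_expressed"
            continue
        if present == species:
            labels[gene] = "universal"
            continue
        label = "other"
        for clade in ordered:
            if mode == "strict":
                hit = present == clade.members
            else:
                hit = present <= clade.members and all(
                    present & sub for sub in subclades[clade.name]
                )
            if hit:
                label = f"{clade.name}-specific"
                break
        labels[gene] = label
    return pd.Series(labels, name="category")
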