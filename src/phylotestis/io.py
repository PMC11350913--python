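"""Alignment container and FASTA/Newick/TSV I/O.

File parsing is delegated to Biopython (FASTA) and dendropy (Newick, via
:class:`~phylotestis.trees.SpeciesTree`); this module enforces the alignment
contract (unique names, equal lengths, upper-case residues) on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Literal, Sequence

from Bio import SeqIO

from .trees import SpeciesTree

logger = logging.getLogger(__name__)

__all__ = ["Alignment", "read_fasta", "write_fasta", "read_newick", "write_newick"]

NUC_ALPHABET = set("ACGTN-")


@dataclass
class Alignment:
    """Named, equal-length sequences; ``mode`` declares the alphabet.

    ``nucleotide`` and ``codon`` share the DNA alphabet; codon mode
    additionally requires a length divisible by 3.  ``protein`` accepts the
    amino-acid alphabet plus gap.
    """

    seqs: Dict[str, str]
    mode: Literal["nucleotide", "codon", "protein"] = "nucleotide"

    def __post_init__(self) -> None:
        lengths = {name: len(s) for name, s in self.seqs.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"ragged alignment: lengths {lengths}")
        if self.mode == "codon" and self.n_columns % 3 != 0:
            raise ValueError(
                f"codon alignment length {self.n_columns} not divisible by 3"
            )
        if self.mode in ("nucleotide", "codon"):
            for name, seq in self.seqs.items():
                bad = set(seq) - NUC_ALPHABET
                if bad:
                    raise ValueError(
                        f"sequence {name!r} has non-nucleotide symbols {sorted(bad)}"
                    )

    @property
    def names(self) -> List[str]:
        return list(self.seqs)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def codon(self, name: str, i: int) -> str:
        return self.seqs[name][3 * i : 3 * i + 3]

    def subset(self, names: Sequence[str]) -> "Alignment":
        return Alignment({n: self.seqs[n] for n in names}, mode=self.mode)

    def columns(self, indices: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given 0-based columns."""
        return Alignment(
            {n: "".join(s[i] for i in indices) for n, s in self.seqs.items()},
            mode="nucleotide" if self.mode == "codon" else self.mode,
        )


def read_fasta(
    path, mode: Literal["nucleotide", "codon", "protein"] = "nucleotide"
) -> Alignment:
    """Read an aligned FASTA file; mixed-case input is upper-cased (logged)."""
    seqs: Dict[str, str] = {}
    n_lower = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {record.id!r}")
        seq = str(record.seq)
        if seq != seq.upper():
            n_lower += 1
            seq = seq.upper()
        seqs[record.id] = seq
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    if n_lower:
        logger.info("%s: upper-cased %d mixed-case sequence(s)", path, n_lower)
    return Alignment(seqs, mode=mode)


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(path) -> SpeciesTree:
    return SpeciesTree.from_file(path)


def write_newick(tree: SpeciesTree, path) -> None:
    tree.write(path)
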