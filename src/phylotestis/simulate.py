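"""Synthetic expression matrices and codon alignments with known truth.

Two generators emulate the statistical structure the downstream analysis
assumes:

* ``simulate_expression_matrix`` plants expression gains at named branches
  of the species tree and optional independent losses below them, then
  draws RPKM values — lognormal (default median 30, log-sd 1) for
  expressed species, uniform sub-cutoff noise for silent ones.  Expressed
  draws below the cutoff are re-drawn by default so the planted truth is
  unambiguous; ``noisy=True`` disables the re-draw to exercise
  cutoff-straddling behaviour.

* ``simulate_codon_alignment`` evolves a stop-free random coding sequence
  along the tree by a per-site Gillespie process: nucleotide changes are
  proposed at kappa-weighted rates, changes creating a stop codon are
  rejected (alignment length is conserved), and nonsynonymous changes are
  accepted at the relative rate omega of the residing branch.  Rates are
  normalised so a branch length of 1 equals one expected nucleotide
  substitution per codon site at uniform codon composition.

Both record a :class:`SimTruth` from which the emitted files are exactly
reproducible given the seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .codonsel import BASES, _TRANSITION, is_stop, translate
from .expression import ExpressionMatrix
from .io import Alignment, write_fasta
from .trees import SpeciesTree, TreeNode

__all__ = [
    "SimScenario",
    "CodonSimParams",
    "SimTruth",
    "simulate_expression_matrix",
    "simulate_codon_alignment",
    "write_fixture_set",
]

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if not is_stop(a + b + c)
)


@dataclass
class SimScenario:
    """Planted gain/loss scenario for the expression generator.

    Genes not assigned to any entry of ``gains`` are planted as universal
    (gained at the root), mirroring the large conserved core of the real
    ortholog table.
    """

    tree: SpeciesTree
    n_genes: int
    gains: Mapping[str, int] = field(default_factory=dict)
    loss_prob: float = 0.0
    expressed_logmean: float = math.log(30.0)
    expressed_logsd: float = 1.0
    silent_scale: float = 0.9
    noisy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        for label in self.gains:
            if label not in self.tree:
                raise ValueError(f"unknown branch label {label!r}")
        if sum(self.gains.values()) > self.n_genes:
            raise ValueError("gain counts exceed n_genes")


@dataclass
class CodonSimParams:
    """Branch-resolved codon evolution parameters.

    ``omega`` must name every non-root branch; branch lengths are expected
    nucleotide substitutions per codon site and live on the tree.
    """

    tree: SpeciesTree
    omega: Mapping[str, float]
    kappa: float = 2.0
    n_codons: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for label, w in self.omega.items():
            if label not in self.tree:
                raise ValueError(f"unknown branch label {label!r}")
            if w < 0:
                raise ValueError(f"omega for {label!r} must be >= 0")
        for node in self.tree.preorder():
            if node.parent is None:
                continue
            if node.label not in self.omega:
                raise ValueError(f"omega missing for branch {node.label!r}")
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative length on branch {node.label!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulation run; replaying ``seed`` regenerates the
    emitted matrix/alignment bit-for-bit."""

    seed: int
    gain_branch: Dict[str, str] = field(default_factory=dict)
    loss_branches: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    omegas: Dict[str, float] = field(default_factory=dict)
    root_sequence: Optional[str] = None
    ancestral_sequences: Dict[str, str] = field(default_factory=dict)
    events: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "gain_branch": self.gain_branch,
            "loss_branches": {g: sorted(v) for g, v in self.loss_branches.items()},
            "omegas": self.omegas,
            "root_sequence": self.root_sequence,
            "ancestral_sequences": self.ancestral_sequences,
            "events": self.events,
        }


# ---------------------------------------------------------------------------
# expression


def simulate_expression_matrix(
    scenario: SimScenario,
) -> Tuple[ExpressionMatrix, SimTruth]:
    """Generate a gene x species RPKM matrix with planted gains/losses."""
    tree = scenario.tree
    rng = np.random.default_rng(scenario.seed)
    species = tree.leaf_names
    truth = SimTruth(seed=scenario.seed)

    gene_plan: List[Tuple[str, str]] = []  # (gene_id, gain branch)
    idx = 0
    for branch, count in scenario.gains.items():
        for _ in range(count):
            idx += 1
            gene_plan.append((f"g{idx:05d}", branch))
    while idx < scenario.n_genes:
        idx += 1
        gene_plan.append((f"g{idx:05d}", tree.root.label))

    rows = []
    for gene_id, gain in gene_plan:
        losses: List[str] = []
        present = {s: False for s in species}

        def descend(node: TreeNode, alive: bool) -> None:
            if alive and node.is_leaf:
                present[node.label] = True
            for child in node.children:
                lost = alive and rng.random() < scenario.loss_prob
                descend(child, alive and not lost)
                if lost:
                    losses.append(child.label)

        gain_node = tree.node(gain)
        if gain_node.is_leaf:
            present[gain_node.label] = True
        descend(gain_node, True)

        values = []
        for s in species:
            if present[s]:
                v = rng.lognormal(scenario.expressed_logmean, scenario.expressed_logsd)
                if not scenario.noisy:
                    while v < 1.0:
                        v = rng.lognormal(
                            scenario.expressed_logmean, scenario.expressed_logsd
                        )
            else:
                v = rng.uniform(0.0, scenario.silent_scale)
            values.append(v)
        rows.append(values)
        truth.gain_branch[gene_id] = gain
        truth.loss_branches[gene_id] = frozenset(losses)

    frame = pd.DataFrame(
        rows, index=[g for g, _ in gene_plan], columns=species, dtype=float
    )
    return ExpressionMatrix(frame), truth


# ---------------------------------------------------------------------------
# codon evolution


@lru_cache(maxsize=None)
def _neighbor_table() -> Dict[str, Tuple[Tuple[str, bool, bool], ...]]:
    """codon -> ((neighbor, is_transition, is_synonymous), ...), stops excluded."""
    table: Dict[str, Tuple[Tuple[str, bool, bool], ...]] = {}
    for codon in SENSE_CODONS:
        entries = []
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                neighbor = codon[:pos] + base + codon[pos + 1 :]
                if is_stop(neighbor):
                    continue
                entries.append(
                    (
                        neighbor,
                        (codon[pos], base) in _TRANSITION,
                        translate(neighbor) == translate(codon),
                    )
                )
        table[codon] = tuple(entries)
    return table


@lru_cache(maxsize=None)
def _branch_rates(omega: float, kappa: float):
    """Per-codon exit rates and neighbour samplers for one (omega, kappa).

    Rates are divided by the mean exit rate over sense codons so that one
    unit of branch length is one expected substitution per codon site at
    uniform composition.
    """
    neighbors = _neighbor_table()
    raw: Dict[str, Tuple[float, List[float], Tuple[Tuple[str, bool, bool], ...]]] = {}
    exit_rates = []
    for codon, entries in neighbors.items():
        rates = [
            (kappa if is_ts else 1.0) * (1.0 if syn else omega)
            for _, is_ts, syn in entries
        ]
        exit_rates.append(sum(rates))
        raw[codon] = (sum(rates), rates, entries)
    rho = float(np.mean(exit_rates))
    scaled = {}
    for codon, (total, rates, entries) in raw.items():
        cum = np.cumsum(rates) / rho
        scaled[codon] = (total / rho, cum, entries)
    return scaled


def _evolve_site(
    codon: str, t: float, rates, rng: np.random.Generator
) -> Tuple[str, int, int]:
    """Gillespie evolution of one codon for time t; returns (codon, n_syn,
    n_nonsyn) events."""
    n_syn = n_nonsyn = 0
    remaining = t
    while remaining > 0:
        total, cum, entries = rates[codon]
        if total <= 0:
            break
        wait = rng.exponential(1.0 / total)
        if wait > remaining:
            break
        remaining -= wait
        u = rng.random() * total
        k = int(np.searchsorted(cum, u, side="right"))
        k = min(k, len(entries) - 1)
        codon, _, syn = entries[k]
        if syn:
            n_syn += 1
        else:
            n_nonsyn += 1
    return codon, n_syn, n_nonsyn


def simulate_codon_alignment(params: CodonSimParams) -> Tuple[Alignment, SimTruth]:
    """Evolve a stop-free coding sequence along the tree; returns the leaf
    alignment (codon mode) and the full ancestral/event truth."""
    rng = np.random.default_rng(params.seed)
    tree = params.tree
    root_codons = [
        SENSE_CODONS[i]
        for i in rng.integers(0, len(SENSE_CODONS), size=params.n_codons)
    ]
    truth = SimTruth(seed=params.seed, omegas=dict(params.omega))
    truth.root_sequence = "".join(root_codons)
    sequences: Dict[str, List[str]] = {tree.root.label: root_codons}
    leaf_seqs: Dict[str, str] = {}

    for node in tree.preorder():
        if node.parent is None:
            if not node.is_leaf:
                truth.ancestral_sequences[node.label] = "".join(root_codons)
            continue
        parent_codons = sequences[node.parent.label]
        length = float(node.length or 0.0)
        rates = _branch_rates(float(params.omega[node.label]), params.kappa)
        child_codons = []
        n_syn = n_nonsyn = 0
        for codon in parent_codons:
            out, s, ns = _evolve_site(codon, length, rates, rng)
            child_codons.append(out)
            n_syn += s
            n_nonsyn += ns
        sequences[node.label] = child_codons
        truth.events[node.label] = {"syn": n_syn, "nonsyn": n_nonsyn}
        if node.is_leaf:
            leaf_seqs[node.label] = "".join(child_codons)
        else:
            truth.ancestral_sequences[node.label] = "".join(child_codons)

    return Alignment(leaf_seqs, mode="codon"), truth


def expected_nonsyn_event_fraction(omega: float, kappa: float) -> float:
    """Expected share of events that are nonsynonymous at uniform codon
    composition (the quantity the event log converges to on short branches)."""
    neighbors = _neighbor_table()
    nonsyn_rate = syn_rate = 0.0
    for entries in neighbors.values():
        for _, is_ts, syn in entries:
            r = kappa if is_ts else 1.0
            if syn:
                syn_rate += r
            else:
                nonsyn_rate += r * omega
    return nonsyn_rate / (nonsyn_rate + syn_rate)


# ---------------------------------------------------------------------------
# fixture emission


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    outdir,
    scenario: SimScenario,
    codon_loci: Optional[Mapping[str, CodonSimParams]] = None,
) -> Dict[str, str]:
    """Emit a complete text fixture set: expression TSV, per-locus FASTA,
    Newick tree, JSON truth and a hash manifest.  Returns {filename: sha256}.
    """
    outdir = str(outdir)
    if os.path.exists(outdir) and not os.path.isdir(outdir):
        raise NotADirectoryError(f"{outdir} exists and is not a directory")
    os.makedirs(outdir, exist_ok=True)

    matrix, expr_truth = simulate_expression_matrix(scenario)
    truth_blob = {"expression": expr_truth.to_jsonable(), "loci": {}}
    files: List[str] = []

    matrix.to_tsv(os.path.join(outdir, "expression.tsv"))
    files.append("expression.tsv")
    scenario.tree.write(os.path.join(outdir, "tree.nwk"))
    files.append("tree.nwk")

    for name, params in (codon_loci or {}).items():
        aln, truth = simulate_codon_alignment(params)
        fasta = f"{name}.fasta"
        write_fasta(aln, os.path.join(outdir, fasta))
        files.append(fasta)
        truth_blob["loci"][name] = truth.to_jsonable()

    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_blob, fh, indent=1, sort_keys=True)
    files.append("truth.json")

    manifest = {f: _sha256(os.path.join(outdir, f)) for f in files}
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        for f, digest in sorted(manifest.items()):
            fh.write(f"{digest}  {f}\n")
    return manifest
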