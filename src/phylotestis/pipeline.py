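"""End-to-end orchestration: expression -> classification -> gain/loss ->
NJ trees -> stem dN/dS -> exact tests, with a reproducible JSON report.

Stages run strictly in order; all results are accumulated in memory and
written only after every stage succeeds, so a failing stage leaves no
partial outputs.  Every number in the report is recomputable from the
inputs, the configuration echo and the seeds it contains.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, Literal, Mapping, Optional, Sequence

import yaml

from . import __version__
from .codonsel import (
    clade_pairwise_dnds,
    selection_asymmetry_test,
    stem_dnds,
)
from .expression import (
    CladeDefinition,
    binarize,
    classify_pattern,
    default_clades,
    read_expression_table,
    universal_set,
)
from .gainloss import aggregate_gainloss
from .io import read_fasta
from .njtree import (
    bootstrap_support,
    compare_clade_rates,
)
from .trees import SpeciesTree

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    expression_tsv: str
    out_dir: str
    alignment_dir: Optional[str] = None
    tree_file: Optional[str] = None
    cutoff: float = 1.0
    clades: Optional[Mapping[str, Sequence[str]]] = None
    classify_mode: Literal["strict", "relaxed", "dollo"] = "strict"
    deletion: Literal["complete", "pairwise"] = "complete"
    bootstrap_replicates: int = 1000
    dnds_mode: Literal["stem", "pairwise"] = "stem"
    correction: Literal["none", "jc"] = "none"
    stem_clades: Sequence[str] = ("Eutheria", "Marsupialia")
    outgroup: str = "chicken"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write ``report.json`` plus TSV summaries.

    Returns the report dict.  Raises :class:`StageError` naming the failing
    stage; nothing is written unless all stages succeed.
    """
    report: dict = {
        "software": {"name": "phylotestis", "version": __version__},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
    }

    # -- expression ------------------------------------------------------
    try:
        matrix = read_expression_table(config.expression_tsv)
        tree = (
            SpeciesTree.from_file(config.tree_file)
            if config.tree_file
            else SpeciesTree.default()
        )
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    if set(matrix.species) != set(tree.leaf_names):
        raise StageError(
            "load",
            "species mismatch between matrix and tree: "
            f"matrix-only {sorted(set(matrix.species) - set(tree.leaf_names))}, "
            f"tree-only {sorted(set(tree.leaf_names) - set(matrix.species))}",
        )

    try:
        pam = binarize(matrix, cutoff=config.cutoff)
        clades = (
            [CladeDefinition.make(n, m) for n, m in config.clades.items()]
            if config.clades
            else default_clades(tree)
        )
        categories = classify_pattern(
            pam, clades, mode=config.classify_mode, tree=tree
        )
        universal = universal_set(pam)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    report["expression"] = {
        "n_genes": len(matrix.gene_ids),
        "n_dropped": matrix.n_dropped,
        "cutoff": config.cutoff,
        "n_universal": len(universal),
        "category_counts": categories.value_counts().to_dict(),
    }

    # -- gain/loss mapping ----------------------------------------------
    try:
        gl_counts, gl_genes = aggregate_gainloss(pam, tree)
    except Exception as exc:
        raise StageError("gainloss", str(exc)) from exc
    report["gainloss"] = {
        branch: {
            "gains": int(gl_counts.loc[branch, "gains"]),
            "losses": int(gl_counts.loc[branch, "losses"]),
        }
        for branch in gl_counts.index
        if gl_counts.loc[branch].sum() > 0
    }

    # -- per-locus molecular evolution ----------------------------------
    loci_report: Dict[str, dict] = {}
    newicks: Dict[str, str] = {}
    if config.alignment_dir:
        fastas = sorted(glob.glob(os.path.join(config.alignment_dir, "*.fasta")))
        for path in fastas:
            locus = os.path.splitext(os.path.basename(path))[0]
            try:
                loci_report[locus], newicks[locus] = _analyse_locus(
                    path, tree, config
                )
            except Exception as exc:
                raise StageError(f"locus:{locus}", str(exc)) from exc
    report["loci"] = loci_report

    # -- emit ------------------------------------------------------------
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    categories.to_csv(
        os.path.join(config.out_dir, "classification.tsv"), sep="\t",
        header=["category"], index_label="gene_id",
    )
    gl_counts.to_csv(
        os.path.join(config.out_dir, "gainloss.tsv"), sep="\t",
        index_label="branch",
    )
    with open(os.path.join(config.out_dir, "gainloss_genes.json"), "w") as fh:
        json.dump(gl_genes, fh, indent=1, sort_keys=True)
    for locus, nwk in newicks.items():
        with open(os.path.join(config.out_dir, f"{locus}.nj.nwk"), "w") as fh:
            fh.write(nwk + "\n")
    return report


def _ng_summary(counts) -> dict:
    return {
        "N": counts.N,
        "S": counts.S,
        "Nd": counts.Nd,
        "Sd": counts.Sd,
        "omega": counts.omega,
        "codons_retained": counts.codons_retained,
        "codons_skipped": counts.codons_skipped,
    }


def _analyse_locus(path: str, tree: SpeciesTree, config: PipelineConfig):
    aln = read_fasta(path, mode="codon")
    missing = set(tree.leaf_names) - set(aln.names)
    if missing:
        raise ValueError(f"alignment missing species {sorted(missing)}")

    nj = bootstrap_support(
        aln,
        replicates=config.bootstrap_replicates,
        seed=config.seed,
        deletion=config.deletion,
    )
    sites = aln.n_columns
    clade_a = tree.clade_leaves(config.stem_clades[0])
    clade_b = tree.clade_leaves(config.stem_clades[1])
    rates = compare_clade_rates(
        nj, clade_a, clade_b, sites, outgroup=config.outgroup
    )

    stems = {}
    for clade in config.stem_clades:
        stems[clade] = stem_dnds(aln, tree, clade, correction=config.correction)
    contrast = selection_asymmetry_test(
        stems[config.stem_clades[0]], stems[config.stem_clades[1]]
    )
    pairwise = {
        clade: clade_pairwise_dnds(
            aln, tree.clade_leaves(clade), correction=config.correction
        )
        for clade in config.stem_clades
    }

    entry = {
        "sites": sites,
        "branch_rate_test": {
            "table": rates.table,
            "p_one_sided": rates.p_one_sided,
            "p_two_sided": rates.p_two_sided,
            "clade_means": {
                config.stem_clades[0]: rates.stats_a.mean,
                config.stem_clades[1]: rates.stats_b.mean,
            },
            "clade_sds": {
                config.stem_clades[0]: rates.stats_a.sd,
                config.stem_clades[1]: rates.stats_b.sd,
            },
            "stem_lengths": {
                config.stem_clades[0]: rates.stats_a.stem_length,
                config.stem_clades[1]: rates.stats_b.stem_length,
            },
        },
        "stem_dnds": {c: _ng_summary(v) for c, v in stems.items()},
        "stem_contrast": {
            "table": contrast.table,
            "p_one_sided": contrast.p_one_sided,
            "p_two_sided": contrast.p_two_sided,
            "no_information": contrast.no_information,
        },
        "pairwise_dnds": {
            c: {
                "mean_omega": r.mean_omega,
                "mean_counts": _ng_summary(r.mean_counts),
            }
            for c, r in pairwise.items()
        },
    }
    return entry, nj.newick(include_support=True)
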