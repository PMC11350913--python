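"""Canonical simulation scenarios of the study design.

These fix the conditions under which the pipeline is exercised end-to-end:
a presence/absence matrix with the observed category sizes planted as
ground truth (22 marsupial-stem gains, 15 therian-stem gains over a
universal background), and a 611-codon locus with an omega shift at the
eutherian stem (0.39) against the marsupial stem (0.10) — the contrast
observed for ARHGAP28 (1833 bp).  Branch lengths are round
therian-divergence-scale values in expected substitutions per codon site;
both stems are 0.3 so the rate contrast is carried by omega alone.
"""

from __future__ import annotations

import math
from typing import Dict

from .simulate import CodonSimParams, SimScenario
from .trees import SpeciesTree

__all__ = [
    "study_branch_lengths",
    "expression_study_scenario",
    "omega_shift_locus_params",
    "uniform_omega_locus_params",
]

EUTHERIAN_STEM_OMEGA = 0.39
MARSUPIAL_STEM_OMEGA = 0.10
BACKGROUND_OMEGA = 0.15
ARHGAP28_CODONS = 611  # 1833 bp


def study_branch_lengths() -> Dict[str, float]:
    """Branch lengths (substitutions per codon site) for the fixed tree."""
    return {
        "chicken": 0.30,
        "platypus": 0.25,
        "Mammalia_stem": 0.10,
        "Theria_stem": 0.10,
        "Marsupialia_stem": 0.30,
        "opossum": 0.10,
        "tasmanian_devil": 0.10,
        "Eutheria_stem": 0.30,
        "mouse": 0.15,
        "Catarrhini_stem": 0.05,
        "macaque": 0.05,
        "Homininae_stem": 0.03,
        "gorilla": 0.03,
        "Hominini_stem": 0.02,
        "human": 0.02,
        "Pan_stem": 0.02,
        "chimpanzee": 0.01,
        "bonobo": 0.01,
    }


def expression_study_scenario(
    seed: int, n_genes: int = 60, loss_prob: float = 0.0
) -> SimScenario:
    """Planted gains matching the observed clade-specific category sizes:
    22 marsupial-stem and 15 therian-stem genes, remainder universal."""
    tree = SpeciesTree.default().set_branch_lengths(study_branch_lengths())
    return SimScenario(
        tree,
        n_genes=n_genes,
        gains={"Marsupialia_stem": 22, "Theria_stem": 15},
        loss_prob=loss_prob,
        expressed_logmean=math.log(30.0),
        expressed_logsd=1.0,
        seed=seed,
    )


def omega_shift_locus_params(seed: int, n_codons: int = ARHGAP28_CODONS) -> CodonSimParams:
    """ARHGAP28-like locus: omega 0.39 at the eutherian stem, 0.10 at the
    marsupial stem, 0.15 elsewhere; kappa 2."""
    tree = SpeciesTree.default().set_branch_lengths(study_branch_lengths())
    omega = {b: BACKGROUND_OMEGA for b in tree.branch_labels if b != "root"}
    omega["Eutheria_stem"] = EUTHERIAN_STEM_OMEGA
    omega["Marsupialia_stem"] = MARSUPIAL_STEM_OMEGA
    return CodonSimParams(tree, omega, kappa=2.0, n_codons=n_codons, seed=seed)


def uniform_omega_locus_params(seed: int, n_codons: int) -> CodonSimParams:
    """Control locus with no stem shift (omega 0.15 on every branch), the
    pattern seen for SYNM (2235 bp) and PDZRN3 (2256 bp)."""
    tree = SpeciesTree.default().set_branch_lengths(study_branch_lengths())
    omega = {b: BACKGROUND_OMEGA for b in tree.branch_labels if b != "root"}
    return CodonSimParams(tree, omega, kappa=2.0, n_codons=n_codons, seed=seed)
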