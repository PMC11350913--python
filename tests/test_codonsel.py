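import itertools

import numpy as np
import pytest
import scipy.stats

from phylotestis import (
    Alignment,
    CodonSimParams,
    SpeciesTree,
    clade_pairwise_dnds,
    fisher_exact,
    fitch_ancestral,
    ng_differences,
    ng_site_counts,
    pair_dnds,
    selection_asymmetry_test,
    simulate_codon_alignment,
    stem_dnds,
)
from phylotestis.codonsel import StopPathwayError, _code

from _oracles import fisher_enumeration, fitch_min_changes, ng_pathway_enumeration
from conftest import arhgap28_like_params

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


# -- site counting ----------------------------------------------------------


def test_phe_codon_site_counts():
    # TTT: only TTT->TTC is synonymous among the nine neighbours
    n, s = ng_site_counts("TTT")
    assert s == pytest.approx(1 / 3)
    assert n == pytest.approx(8 / 3)


def test_met_codon_has_no_synonymous_sites():
    n, s = ng_site_counts("ATG")
    assert s == 0.0
    assert n == 3.0


def test_site_counts_always_sum_to_three():
    for codon in SENSE:
        n, s = ng_site_counts(codon)
        assert n + s == pytest.approx(3.0)
        assert s >= 0


def test_site_counts_reject_stops_and_gaps():
    with pytest.raises(ValueError):
        ng_site_counts("TAA")
    with pytest.raises(ValueError):
        ng_site_counts("A-G")


# -- difference counting ----------------------------------------------------


def test_identical_codons_have_no_differences():
    assert ng_differences("AAA", "AAA") == (0.0, 0.0)


def test_single_synonymous_step():
    assert ng_differences("TTT", "TTC") == (0.0, 1.0)


def test_two_step_pathway_average():
    nd, sd = ng_differences("TTT", "GTA")
    code, stops = _code(1)
    exp_nd, exp_sd = ng_pathway_enumeration("TTT", "GTA", code, stops)
    assert (nd, sd) == (exp_nd, exp_sd)
    assert nd + sd == 2.0


def test_differences_symmetric_and_sum_to_hamming():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b = rng.choice(SENSE, 2)
        try:
            nd, sd = ng_differences(a, b)
        except StopPathwayError:
            continue
        nd2, sd2 = ng_differences(b, a)
        assert (nd, sd) == pytest.approx((nd2, sd2))
        hamming = sum(x != y for x, y in zip(a, b))
        assert nd + sd == pytest.approx(hamming)


# -- pairwise dN/dS ---------------------------------------------------------


def test_pair_dnds_identical_sequences():
    seq = "ATGTTTAAACCC"
    counts = pair_dnds(seq, seq)
    assert counts.Nd == counts.Sd == 0
    assert counts.omega is None
    assert counts.N + counts.S == pytest.approx(3 * counts.codons_retained)


def test_pair_dnds_sites_identity_on_random_sequences():
    rng = np.random.default_rng(5)
    a = "".join(rng.choice(SENSE, 50))
    b = "".join(rng.choice(SENSE, 50))
    counts = pair_dnds(a, b)
    assert counts.N + counts.S == pytest.approx(3 * counts.codons_retained)


def test_pair_dnds_skips_gap_and_stop_columns():
    counts = pair_dnds("ATG---TTT" + "TAA", "ATGAAATTC" + "AAA")
    assert counts.codons_skipped == {"gap": 1, "stop": 1}
    assert counts.codons_retained == 2


def test_pair_dnds_neutral_simulation_recovers_omega_one():
    """Pairwise omega on neutral simulations is centred on 1 within the
    binomial error of the difference counts.

    Run at kappa = 1: Nei–Gojobori counting weights all changes equally,
    so a transition/transversion bias in the generator shifts its neutral
    expectation below 1 (a known property of the estimator, separately
    visible in the scenario simulations)."""
    tree = SpeciesTree.from_newick("(a:0.15,b:0.15)root;")
    omega = {"a": 1.0, "b": 1.0}
    estimates = []
    for seed in range(10):
        aln, _ = simulate_codon_alignment(
            CodonSimParams(tree, omega, kappa=1.0, n_codons=3000, seed=seed)
        )
        counts = pair_dnds(aln.seqs["a"], aln.seqs["b"])
        estimates.append(counts.omega)
    mean = float(np.mean(estimates))
    se = float(np.std(estimates, ddof=1) / np.sqrt(len(estimates)))
    assert abs(mean - 1.0) < 3 * max(se, 0.02)


# -- Fitch ancestral reconstruction ----------------------------------------


def quartet_tree():
    return SpeciesTree.from_newick("((A,B)ab,(C,D)cd)root;")


def test_fitch_uniform_column_resolves_everywhere():
    tree = quartet_tree()
    aln = Alignment({n: "TTT" for n in "ABCD"}, mode="codon")
    anc = fitch_ancestral(aln, tree)
    for label in ("ab", "cd", "root"):
        assert anc.resolved[label] == ["TTT"]
    assert anc.n_changes == 0


def test_fitch_split_column_root_ambiguous():
    tree = quartet_tree()
    aln = Alignment(
        {"A": "TTT", "B": "TTT", "C": "TTC", "D": "TTC"}, mode="codon"
    )
    anc = fitch_ancestral(aln, tree)
    assert anc.state_sets["root"][0] == frozenset({"TTT", "TTC"})
    assert anc.resolved["root"][0] is None
    assert anc.resolved["ab"][0] == "TTT"
    assert anc.resolved["cd"][0] == "TTC"
    assert anc.n_changes == 1


def test_fitch_change_count_matches_exhaustive_minimisation():
    newick = "(((A,B)ab,C)abc,(D,(E,F)ef)def)root;"
    tree = SpeciesTree.from_newick(newick)
    rng = np.random.default_rng(17)
    states = ["AAA", "AAC", "ACA"]
    for _ in range(30):
        leaf_codons = {leaf: str(rng.choice(states)) for leaf in tree.leaf_names}
        aln = Alignment(dict(leaf_codons), mode="codon")
        anc = fitch_ancestral(aln, tree)
        assert anc.n_changes == fitch_min_changes(leaf_codons, tree)


def test_fitch_rejects_leaf_mismatch():
    tree = quartet_tree()
    with pytest.raises(ValueError, match="missing"):
        fitch_ancestral(Alignment({"A": "TTT"}, mode="codon"), tree)


# -- stem dN/dS -------------------------------------------------------------


def test_stem_dnds_zero_length_stem_has_no_differences(species_tree):
    lengths = {b: 0.1 for b in species_tree.branch_labels if b != "root"}
    lengths["Eutheria_stem"] = 0.0
    tree = SpeciesTree.default().set_branch_lengths(lengths)
    omega = {b: 0.5 for b in tree.branch_labels if b != "root"}
    aln, _ = simulate_codon_alignment(
        CodonSimParams(tree, omega, n_codons=200, seed=4)
    )
    counts = stem_dnds(aln, tree, "Eutheria")
    # ancestral-state errors may leave a residue of apparent change, but a
    # zero-length stem cannot carry real substitutions
    assert counts.Nd + counts.Sd <= 2


def test_stem_dnds_single_shared_derived_nonsynonymous_change(species_tree):
    """All eutherians share one derived nonsynonymous codon: the eutherian
    stem carries exactly that change."""
    eutherians = set(species_tree.clade_leaves("Eutheria"))
    seqs = {}
    for leaf in species_tree.leaf_names:
        # ancestral AAA (Lys); eutherians carry GAA (Glu) at codon 2
        second = "GAA" if leaf in eutherians else "AAA"
        seqs[leaf] = "ATG" + second + "TTT"
    aln = Alignment(seqs, mode="codon")
    counts = stem_dnds(aln, species_tree, "Eutheria")
    assert counts.Nd == 1.0
    assert counts.Sd == 0.0


def test_stem_dnds_column_accounting(species_tree):
    params = arhgap28_like_params(seed=0, n_codons=200)
    aln, _ = simulate_codon_alignment(params)
    counts = stem_dnds(aln, params.tree, "Eutheria")
    dropped = sum(counts.codons_skipped.values())
    assert counts.codons_retained + dropped == 200


def test_stem_dnds_unknown_clade(species_tree):
    aln = Alignment({n: "AAA" for n in species_tree.leaf_names}, mode="codon")
    with pytest.raises(KeyError, match="Afrotheria"):
        stem_dnds(aln, species_tree, "Afrotheria")


# -- Fisher exact test ------------------------------------------------------


def test_fisher_degenerate_margin_is_one():
    res = fisher_exact([[0, 5], [0, 7]])
    assert res.p_one_sided == res.p_two_sided == 1.0


def test_fisher_hand_enumerated_table():
    res = fisher_exact([[3, 1], [1, 3]])
    assert res.p_two_sided == pytest.approx(34 / 70)


def test_fisher_matches_enumeration_and_scipy_on_sweep():
    """Exact agreement with an independent factorial enumeration (and with
    scipy) over all 2x2 tables with total <= 12."""
    for total in range(13):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    table = [[a, b], [c, d]]
                    res = fisher_exact(table)
                    p_one, p_two = fisher_enumeration(table)
                    assert res.p_one_sided == pytest.approx(p_one, abs=1e-12)
                    assert res.p_two_sided == pytest.approx(p_two, abs=1e-12)
                    sp = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
                    assert res.p_two_sided == pytest.approx(sp, abs=1e-9)


def test_fisher_rejects_negative_entries():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])


# -- selection asymmetry ----------------------------------------------------


def test_selection_asymmetry_identical_counts_p_one():
    from phylotestis.codonsel import NGCounts

    a = NGCounts(N=100, S=50, Nd=10, Sd=10)
    res = selection_asymmetry_test(a, a)
    assert res.p_two_sided == 1.0


def test_selection_asymmetry_matches_oracle():
    from phylotestis.codonsel import NGCounts

    a = NGCounts(N=100, S=50, Nd=30, Sd=10)
    b = NGCounts(N=100, S=50, Nd=3, Sd=10)
    res = selection_asymmetry_test(a, b)
    p_one, p_two = fisher_enumeration([[30, 10], [3, 10]])
    assert res.p_one_sided == pytest.approx(p_one)
    assert res.p_two_sided == pytest.approx(p_two)


def test_selection_asymmetry_all_zero_flags_no_information():
    from phylotestis.codonsel import NGCounts

    res = selection_asymmetry_test(NGCounts(), NGCounts())
    assert res.p_two_sided == 1.0
    assert res.no_information


# -- clade pairwise dN/dS ---------------------------------------------------


def test_clade_pairwise_two_members_equals_single_pair(species_tree):
    params = arhgap28_like_params(seed=1, n_codons=150)
    aln, _ = simulate_codon_alignment(params)
    res = clade_pairwise_dnds(aln, ["opossum", "tasmanian_devil"])
    direct = pair_dnds(aln.seqs["opossum"], aln.seqs["tasmanian_devil"])
    assert res.mean_omega == pytest.approx(direct.omega)
    assert res.mean_counts.Nd == pytest.approx(direct.Nd)


def test_clade_pairwise_mean_consistent_with_stored_pairs(species_tree):
    params = arhgap28_like_params(seed=2, n_codons=150)
    aln, _ = simulate_codon_alignment(params)
    clade = species_tree.clade_leaves("Eutheria")
    res = clade_pairwise_dnds(aln, clade)
    assert len(res.pairs) == 15
    omegas = [r.omega for r in res.pairs.values() if r.omega is not None]
    assert res.mean_omega == pytest.approx(float(np.mean(omegas)))


def test_clade_pairwise_identical_sequences():
    aln = Alignment({"x": "ATGAAA", "y": "ATGAAA"}, mode="codon")
    res = clade_pairwise_dnds(aln, ["x", "y"])
    assert res.mean_counts.Nd == 0
    assert res.mean_omega is None


def test_clade_pairwise_rejects_singleton():
    aln = Alignment({"x": "ATGAAA"}, mode="codon")
    with pytest.raises(ValueError):
        clade_pairwise_dnds(aln, ["x"])
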