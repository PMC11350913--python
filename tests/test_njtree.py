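import numpy as np
import pytest

from phylotestis import (
    Alignment,
    CodonSimParams,
    DistanceMatrix,
    SpeciesTree,
    bootstrap_support,
    clade_branch_stats,
    count_differences,
    distance_matrix,
    neighbor_joining,
    rate_asymmetry_test,
    simulate_codon_alignment,
)
from phylotestis.njtree import complete_deletion_mask

from _oracles import fisher_enumeration, random_additive_tree


# -- difference counting ----------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
)
def test_count_differences_basic(a, b, expected):
    assert count_differences(a, b) == expected


def test_count_differences_pairwise_deletion_skips_gap_columns():
    # only the 3 columns where both are non-gap are compared
    assert count_differences("AC-T", "ACGT", deletion="pairwise") == 0
    assert count_differences("AC-T", "ACGA", deletion="pairwise") == 1


def test_count_differences_length_mismatch():
    with pytest.raises(ValueError):
        count_differences("ACG", "AC")


def test_complete_deletion_uses_alignment_wide_mask():
    aln = Alignment({"a": "ACGT", "b": "AC-T", "c": "ACGA"})
    mask = complete_deletion_mask(aln)
    assert mask == [0, 1, 3]
    assert count_differences("ACGT", "ACGA", deletion="complete", mask=mask) == 1


def test_distance_matrix_matches_scalar_counts():
    rng = np.random.default_rng(0)
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT-"), 60)) for i in range(5)
    }
    aln = Alignment(seqs)
    for deletion in ("complete", "pairwise"):
        dm = distance_matrix(aln, deletion=deletion)
        mask = complete_deletion_mask(aln) if deletion == "complete" else None
        for i, x in enumerate(dm.labels):
            for j, y in enumerate(dm.labels):
                expected = count_differences(
                    seqs[x], seqs[y], deletion=deletion, mask=mask
                )
                assert dm.matrix[i, j] == expected


def test_distance_matrix_identical_sequences_is_zero():
    aln = Alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
    assert distance_matrix(aln).matrix.sum() == 0


def test_distance_matrix_needs_three_sequences():
    with pytest.raises(ValueError):
        distance_matrix(Alignment({"a": "ACGT", "b": "ACGT"}))


# -- neighbor joining -------------------------------------------------------


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
    tree = neighbor_joining(d)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}


def test_nj_four_taxa_additive_example():
    labels = ["A", "B", "C", "D"]
    m = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = neighbor_joining(DistanceMatrix(labels, m))
    assert tree.splits() == frozenset({frozenset({"C", "D"})})
    back = tree.leaf_distances()
    assert back.labels == labels
    np.testing.assert_allclose(back.matrix, m)


def test_nj_exact_on_random_additive_matrices():
    for seed in range(20):
        truth = random_additive_tree(10, np.random.default_rng(seed))
        dm = truth.leaf_distances()
        out = neighbor_joining(dm)
        assert out.splits() == truth.splits()
        np.testing.assert_allclose(out.leaf_distances().matrix, dm.matrix, atol=1e-9)


def test_nj_invariant_under_label_permutation():
    truth = random_additive_tree(8, np.random.default_rng(42))
    dm = truth.leaf_distances()
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(dm.labels))
    dm2 = DistanceMatrix(
        [dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
    )
    assert neighbor_joining(dm2).splits() == neighbor_joining(dm).splits()


def test_nj_topology_agrees_with_skbio_on_random_matrices():
    """Independent implementation cross-check: scikit-bio's NJ finds the
    same unrooted topology on random additive matrices."""
    import skbio

    for seed in range(5):
        truth = random_additive_tree(8, np.random.default_rng(100 + seed))
        dm = truth.leaf_distances()
        ours = neighbor_joining(dm).splits()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
        leaves = frozenset(dm.labels)
        ref = min(leaves)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(leaves) - 2:
                theirs.add(below if ref not in below else leaves - below)
        assert ours == frozenset(theirs)


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))


def test_negative_branch_clamp_preserves_total_length():
    # violating the triangle inequality forces a negative NJ branch
    m = np.array(
        [[0, 1, 10, 9], [1, 0, 9, 10], [10, 9, 0, 1], [9, 10, 1, 0]], dtype=float
    )
    tree = neighbor_joining(DistanceMatrix(list("abcd"), m))
    lengths = []

    def walk(node):
        lengths.append(node.length)
        for c in node.children:
            walk(c)

    walk(tree.root)
    assert all(l >= 0 for l in lengths)


# -- bootstrap --------------------------------------------------------------


def _clean_alignment(seed, n_codons=600):
    newick = "((a:0.08,b:0.08)ab:0.1,((c:0.08,d:0.08)cd:0.1,(e:0.08,f:0.08)ef:0.1)cdef:0.05)root;"
    tree = SpeciesTree.from_newick(newick)
    omega = {b: 0.3 for b in tree.branch_labels if b != "root"}
    aln, _ = simulate_codon_alignment(
        CodonSimParams(tree, omega, n_codons=n_codons, seed=seed)
    )
    return aln


def test_bootstrap_reproducible_and_bounded():
    aln = _clean_alignment(0, n_codons=100)
    t1 = bootstrap_support(aln, replicates=50, seed=9)
    t2 = bootstrap_support(aln, replicates=50, seed=9)
    assert t1.support == t2.support
    assert all(0.0 <= v <= 100.0 for v in t1.support.values())


def test_bootstrap_high_support_on_clean_signal():
    """With ~1800 cleanly simulated sites every true bipartition should be
    recovered with high support."""
    for seed in range(3):
        aln = _clean_alignment(seed)
        tree = bootstrap_support(aln, replicates=100, seed=seed)
        assert len(tree.support) == 3
        assert all(v >= 95.0 for v in tree.support.values())


# -- clade statistics and the rate test ------------------------------------


def test_clade_branch_stats_two_leaves():
    from phylotestis.njtree import PhyloTree, _Node

    leaves = {name: _Node(name, l) for name, l in
              [("x", 2.0), ("y", 4.0), ("out", 1.0), ("z", 1.0)]}
    inner = _Node(None, 1.0)
    inner.children = [leaves["x"], leaves["y"]]
    root = _Node()
    root.children = [leaves["out"], leaves["z"], inner]
    stats = clade_branch_stats(PhyloTree(root), ["x", "y"], outgroup="out")
    assert stats.lengths == [2.0, 4.0] or stats.lengths == [4.0, 2.0]
    assert stats.mean == 3.0
    assert stats.sd == 1.0
    assert stats.stem_length == 1.0


def test_clade_branch_stats_rejects_non_monophyletic():
    from phylotestis.njtree import PhyloTree, _Node

    a, b, c, out = (_Node(n, 1.0) for n in ("a", "b", "c", "out"))
    inner = _Node(None, 1.0)
    inner.children = [a, b]
    root = _Node()
    root.children = [out, c, inner]
    with pytest.raises(ValueError, match="monophyletic"):
        clade_branch_stats(PhyloTree(root), ["a", "c"], outgroup="out")


def test_rate_asymmetry_identical_rows_p_one():
    res = rate_asymmetry_test(12, 12, sites=600)
    assert res.p_two_sided == 1.0


def test_rate_asymmetry_matches_enumeration_oracle():
    res = rate_asymmetry_test(30, 5, sites=600)
    p_one, p_two = fisher_enumeration([[30, 570], [5, 595]])
    assert res.p_one_sided == pytest.approx(p_one, rel=1e-9)
    assert res.p_two_sided == pytest.approx(p_two, rel=1e-9)


def test_rate_asymmetry_rejects_invalid_counts():
    with pytest.raises(ValueError):
        rate_asymmetry_test(-1, 5, sites=600)
    with pytest.raises(ValueError):
        rate_asymmetry_test(700, 5, sites=600)


def test_sixfold_stem_asymmetry_power():
    """A six-fold rate contrast at 1833 sites is detected (one-sided
    p < 0.05) in at least 90% of simulated replicates."""
    rng = np.random.default_rng(2024)
    sites = 1833
    detected = 0
    n_rep = 100
    for _ in range(n_rep):
        k_fast = rng.binomial(sites, 6 * 0.02)
        k_slow = rng.binomial(sites, 0.02)
        res = rate_asymmetry_test(k_fast, k_slow, sites=sites)
        if res.p_one_sided < 0.05:
            detected += 1
    assert detected >= 90
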