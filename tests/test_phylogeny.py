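"""Alignment, distances, neighbor joining and bootstrap."""

import numpy as np
import pytest

from wrkycensus._exhaustive import best_ls_topology, random_additive_matrix
from wrkycensus.phylogeny import (
    DistanceMatrix,
    DomainAlignment,
    align_progressive,
    bootstrap,
    nj_tree,
    p_distance,
)


def test_identical_sequences_align_gapless():
    aln = align_progressive(["a", "b", "c"], ["WRKYGQK"] * 3)
    assert aln.rows == ["WRKYGQK"] * 3


def test_single_deletion_gives_one_gap_column():
    aln = align_progressive(["a", "b"], ["WRKYGQK", "WRKYGK"])
    assert sum("-" in col for col in zip(*aln.rows)) == 1
    assert aln.ungapped(0) == "WRKYGQK" and aln.ungapped(1) == "WRKYGK"


def test_alignment_width_and_round_trip_property():
    rng = np.random.default_rng(3)
    AA = "ACDEFGHIKLMNPQRSTVWY"
    seqs = [
        "".join(AA[i] for i in rng.integers(0, 20, size=int(rng.integers(20, 40))))
        for _ in range(5)
    ]
    aln = align_progressive(list("abcde"), seqs)
    assert aln.n_columns >= max(len(s) for s in seqs)
    for k, s in enumerate(seqs):
        assert aln.ungapped(k) == s


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_progressive(["a", "b"], ["WRKY", ""])


def test_p_distance_hand_counts():
    aln = DomainAlignment(["a", "b"], ["AAAA", "AAAT"])
    assert p_distance(aln).matrix[0, 1] == pytest.approx(0.25)
    gapped = DomainAlignment(["a", "b"], ["AA-A", "AATA"])
    assert p_distance(gapped).matrix[0, 1] == pytest.approx(0.0)
    mism = DomainAlignment(["a", "b"], ["AG-A", "AATA"])
    assert p_distance(mism).matrix[0, 1] == pytest.approx(1 / 3)


def test_p_distance_identical_rows_zero_and_no_overlap_error():
    aln = DomainAlignment(["a", "b"], ["WRKY", "WRKY"])
    assert p_distance(aln).matrix[0, 1] == 0.0
    disjoint = DomainAlignment(["a", "b"], ["AA--", "--TT"])
    with pytest.raises(ValueError, match="a.*b"):
        p_distance(disjoint)


def test_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = nj_tree(dm)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_four_taxon_topology_recovery():
    # distances from tree ((A:1,B:2):1,(C:3,D:4))
    ids = ["A", "B", "C", "D"]
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    # branch lengths reproduce the generating path distances exactly
    pd_ = tree.path_distances()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert pd_[(a, b)] == pytest.approx(d[ids.index(a), ids.index(b)])


def test_nj_matches_exhaustive_least_squares_on_additive_matrices():
    """On 100 random additive matrices (n = 4 or 5), NJ recovers the
    generating topology — agreeing with exhaustive least-squares search
    — and reconstructs branch lengths exactly."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(4, 6))
        labels = [f"T{i}" for i in range(n)]
        dmat, true_bips = random_additive_matrix(labels, rng)
        tree = nj_tree(DistanceMatrix(labels, dmat))
        ls_bips, _ = best_ls_topology(labels, dmat)
        assert tree.bipartitions() == true_bips == ls_bips
        pd_ = tree.path_distances()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert pd_[(a, b)] == pytest.approx(
                    dmat[labels.index(a), labels.index(b)], abs=1e-9
                )


def test_asymmetric_matrix_rejected():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


def test_negative_branch_lengths_clamped():
    # a non-additive matrix known to produce a negative NJ length
    ids = list("ABCD")
    d = np.array(
        [[0, 1, 10, 10], [1, 0, 10, 10], [10, 10, 0, 1], [10, 10, 1, 0]], float
    )
    tree = nj_tree(DistanceMatrix(ids, d))
    def all_lengths(node):
        yield node.length
        for c in node.children:
            yield from all_lengths(c)
    assert all(l >= 0 for l in all_lengths(tree))


def _clean_alignment():
    # four 2-leaf groups, strongly separated, no homoplasy
    rows = {
        "a1": "AAAAAAAAAACCCCCCCCCC",
        "a2": "AAAAAAAAAACCCCCCCCCG",
        "b1": "TTTTTTTTTTGGGGGGGGGG",
        "b2": "TTTTTTTTTTGGGGGGGGGC",
        "c1": "AAAAATTTTTAAAAATTTTT",
        "c2": "AAAAATTTTTAAAAATTTTG",
    }
    return DomainAlignment(list(rows), list(rows.values()))


def test_bootstrap_supports_are_full_for_clean_groups():
    tree = bootstrap(_clean_alignment(), replicates=50, seed=1)
    supports = [n.support for n in tree.iter_internal() if n.support is not None]
    assert supports and all(s > 95 for s in supports)


def test_bootstrap_is_seed_deterministic():
    t1 = bootstrap(_clean_alignment(), replicates=30, seed=9)
    t2 = bootstrap(_clean_alignment(), replicates=30, seed=9)
    assert t1.to_newick() == t2.to_newick()


def test_bootstrap_supports_stable_across_replicate_counts():
    """Support estimates at 100 and 400 replicates agree within
    Monte-Carlo error on a clean alignment."""
    aln = _clean_alignment()

    def supports(tree):
        out = {}
        for node in tree.iter_internal():
            bp = tree._bipartition_of(node)
            if bp is not None and node.support is not None:
                out[bp] = node.support
        return out

    s100 = supports(bootstrap(aln, 100, seed=3))
    s400 = supports(bootstrap(aln, 400, seed=4))
    assert set(s100) == set(s400)
    for bp in s100:
        assert abs(s100[bp] - s400[bp]) <= 15


def test_bipartitions_invariant_to_leaf_order():
    aln = _clean_alignment()
    rev = DomainAlignment(aln.ids[::-1], aln.rows[::-1])
    t1 = nj_tree(p_distance(aln))
    t2 = nj_tree(p_distance(rev))
    assert t1.bipartitions() == t2.bipartitions()


def test_newick_output_parses_with_dendropy():
    import dendropy

    tree = bootstrap(_clean_alignment(), replicates=10, seed=2)
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(
        tree.leaf_names()
    )
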