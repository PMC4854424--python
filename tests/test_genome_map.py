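"""Family naming, cluster detection and tandem-duplicate calling."""

import itertools

import numpy as np
import pytest

from wrkycensus.genome_map import (
    GeneLocus,
    alignment_identity,
    assign_names,
    detect_clusters,
    detect_tandem,
)


def _locus(gid, chrom, start, end=None):
    return GeneLocus(gid, chrom, start, end if end is not None else start + 1000)


def test_naming_sorts_by_chromosome_then_start():
    loci = [_locus("a", "chr2", 5000), _locus("b", "chr1", 9000), _locus("c", "chr1", 100)]
    assign_names(loci)
    names = {l.gene_id: l.name for l in loci}
    assert names == {"c": "FvWRKY01", "b": "FvWRKY02", "a": "FvWRKY03"}


def test_unplaced_loci_numbered_last():
    loci = [_locus(f"g{i}", f"chr{1 + i % 7}", 1000 * i) for i in range(58)]
    loci.append(GeneLocus("orphan", "unplaced", 0, 0))
    assign_names(loci)
    assert next(l for l in loci if l.gene_id == "orphan").name == "FvWRKY59"


def test_naming_is_input_order_invariant_and_bijective():
    rng = np.random.default_rng(4)
    loci = [_locus(f"g{i}", f"chr{1 + i % 3}", int(rng.integers(0, 10**6))) for i in range(20)]
    assign_names(loci)
    baseline = {l.gene_id: l.name for l in loci}
    shuffled = list(loci)
    rng.shuffle(shuffled)
    for l in shuffled:
        l.name = None
    assign_names(shuffled)
    assert {l.gene_id: l.name for l in shuffled} == baseline
    assert len(set(baseline.values())) == len(baseline)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        assign_names([_locus("a", "chr1", 0), _locus("a", "chr1", 5000)])


def test_cluster_within_threshold_detected_and_brute_force_checked():
    loci = [_locus("a", "chr1", 0), _locus("b", "chr1", 150_000)]
    (cluster,) = detect_clusters(loci, 200_000)
    assert cluster.members == ["a", "b"]
    # brute force: all pairwise start distances within the cluster chain
    for x, y in itertools.combinations(cluster.members, 2):
        sa = next(l.start for l in loci if l.gene_id == x)
        sb = next(l.start for l in loci if l.gene_id == y)
        assert abs(sa - sb) <= 200_000


def test_cluster_beyond_threshold_or_cross_chromosome_not_detected():
    assert detect_clusters([_locus("a", "chr1", 0), _locus("b", "chr1", 250_000)], 200_000) == []
    assert detect_clusters([_locus("a", "chr1", 0), _locus("b", "chr2", 0)], 200_000) == []


def test_cluster_chaining_and_singleton_isolation():
    loci = [
        _locus("a", "chr1", 0),
        _locus("b", "chr1", 180_000),
        _locus("c", "chr1", 360_000),   # chained via b
        _locus("d", "chr1", 900_000),   # isolated
    ]
    (cluster,) = detect_clusters(loci, 200_000)
    assert cluster.members == ["a", "b", "c"]
    # the discarded singleton is not within threshold of any member
    for m in cluster.members:
        s = next(l.start for l in loci if l.gene_id == m)
        assert abs(900_000 - s) > 200_000


def test_nonpositive_gap_is_configuration_error():
    with pytest.raises(ValueError):
        detect_clusters([_locus("a", "chr1", 0)], 0)


def test_tandem_pair_detection_and_negatives():
    base = "MKVLAWRKYGQKEEILKAFDPTNSSFGHKLMRQ" * 3
    variant = base[:-2] + "GG"          # high identity
    unrelated = "MSTQPLDNGAEEVVRKAAAGGGNDDDLLLQQQ" * 3
    loci = [
        _locus("a", "chr1", 0, 2000),
        _locus("b", "chr1", 4000, 6000),
        _locus("c", "chr2", 0, 2000),
        _locus("d", "chr2", 4000, 6000),
    ]
    seqs = {"a": base, "b": variant, "c": base, "d": unrelated}
    pairs = detect_tandem(loci, seqs, min_similarity=0.7, max_intervening=1)
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("a", "b")]
    assert pairs[0].identity > 0.9

    # same pair split across chromosomes: no call
    loci2 = [_locus("a", "chr1", 0, 2000), _locus("b", "chr2", 0, 2000)]
    assert detect_tandem(loci2, seqs, 0.7, 1) == []


def test_tandem_intervening_gene_limit():
    seq = "MKVLAWRKYGQKEEILKAFDPTNSSFGHKLMRQ" * 3
    fam = [_locus("a", "chr1", 0, 2000), _locus("b", "chr1", 40_000, 42_000)]
    fillers = [_locus(f"x{i}", "chr1", 5_000 + 4_000 * i, 7_000 + 4_000 * i) for i in range(3)]
    seqs = {"a": seq, "b": seq}
    assert detect_tandem(fam, seqs, 0.7, max_intervening=1, all_loci=fam + fillers) == []
    assert len(detect_tandem(fam, seqs, 0.7, max_intervening=3, all_loci=fam + fillers)) == 1


def test_missing_sequence_is_error():
    loci = [_locus("a", "chr1", 0), _locus("b", "chr1", 2000)]
    with pytest.raises(ValueError, match="b"):
        detect_tandem(loci, {"a": "MKV"}, 0.7, 1)


def test_identity_of_identical_and_disjoint_sequences():
    assert alignment_identity("MKVLA", "MKVLA") == 1.0
    assert alignment_identity("MKVLA", "MKVIA") == pytest.approx(0.8)


def test_planted_cluster_and_tandem_round_trip(tmp_path):
    """Generator-planted clusters and tandem pairs are exactly the ones
    detected (single-linkage 200 kb, adjacency + identity)."""
    from wrkycensus.gene_structure import build_models
    from wrkycensus.synthetic_data import gen_genome

    gff, truth = gen_genome(
        n_genes=9,
        n_chromosomes=3,
        cluster_plan=[("chr1", 3, 180_000), ("chr2", 2, 150_000)],
        tandem_pairs=1,
        seed=13,
        chromosome_size=4_000_000,
    )
    path = tmp_path / "g.gff3"
    path.write_text(gff)
    models = build_models(str(path))
    loci = [
        GeneLocus(m.gene_id, m.chromosome, min(s for s, _ in m.cds),
                  max(e for _, e in m.cds), m.strand)
        for m in models
    ]
    detected = {frozenset(c.members) for c in detect_clusters(loci)}
    planted = {
        frozenset(g for g, t in truth.genes.items() if t.cluster_id == cid)
        for cid in {t.cluster_id for t in truth.genes.values() if t.cluster_id}
    }
    assert detected == planted

    seqs = {gid: t.protein for gid, t in truth.genes.items()}
    pairs = {frozenset((p.gene_a, p.gene_b)) for p in detect_tandem(loci, seqs)}
    planted_pairs = {
        frozenset(g for g, t in truth.genes.items() if t.tandem_pair_id == pid)
        for pid in {t.tandem_pair_id for t in truth.genes.values() if t.tandem_pair_id}
    }
    assert pairs == planted_pairs
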