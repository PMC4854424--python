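"""Chromosomal organization: naming, gene clusters, tandem duplicates.

Family members are renamed in order of their placement along the
chromosomes (natural chromosome order, then start coordinate), with
unplaced loci numbered last — the convention used for plant gene-family
censuses.  Clusters follow the Holub definition, implemented as
single-linkage chains of loci whose start-to-start distance stays
within a configurable gap (200 kb default).  Tandem duplicates are
same-chromosome pairs with at most a configured number of intervening
genes and global-alignment identity above a threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_CLUSTER_GAP = 200_000
DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MAX_INTERVENING = 1

UNPLACED = "unplaced"


@dataclass
class GeneLocus:
    gene_id: str
    chromosome: str          # chromosome name or "unplaced"
    start: int               # 0-based half-open genomic
    end: int
    strand: str = "+"
    name: str | None = None  # assigned family name

    def __post_init__(self):
        if self.chromosome != UNPLACED and self.start >= self.end:
            raise ValueError(f"locus {self.gene_id}: start >= end")

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass
class GeneCluster:
    chromosome: str
    members: list[str]       # gene ids sorted by start

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TandemPair:
    gene_a: str
    gene_b: str
    identity: float
    intervening: int


def _natural_key(chrom: str):
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def assign_names(
    loci: list[GeneLocus], prefix: str = "FvWRKY", width: int = 2
) -> list[GeneLocus]:
    """Number loci 1..k by (chromosome, start); unplaced loci last.

    Returns the same loci with ``name`` set; input order is preserved.
    Raises on duplicate gene ids.
    """
    ids = [l.gene_id for l in loci]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dup}")
    placed = [l for l in loci if l.placed]
    placed.sort(key=lambda l: (_natural_key(l.chromosome), l.start, l.gene_id))
    counter = 0
    for locus in placed:
        counter += 1
        locus.name = f"{prefix}{counter:0{width}d}"
    for locus in loci:
        if not locus.placed:
            counter += 1
            locus.name = f"{prefix}{counter:0{width}d}"
    return loci


def detect_clusters(
    loci: list[GeneLocus], max_gap_bp: int = DEFAULT_CLUSTER_GAP
) -> list[GeneCluster]:
    """Single-linkage chains of placed loci within the gap threshold.

    Consecutive loci on one chromosome join a chain when their
    start-to-start distance is <= ``max_gap_bp``; singletons are
    discarded.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        if l.placed:
            by_chrom.setdefault(l.chromosome, []).append(l)
    clusters = []
    for chrom in sorted(by_chrom, key=_natural_key):
        members = sorted(by_chrom[chrom], key=lambda l: l.start)
        chain = [members[0]]
        for prev, cur in zip(members, members[1:]):
            if cur.start - prev.start <= max_gap_bp:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(GeneCluster(chrom, [l.gene_id for l in chain]))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(GeneCluster(chrom, [l.gene_id for l in chain]))
    return clusters


_aligner = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        _aligner = a
    return _aligner


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Identity of the optimal global alignment: matches / columns."""
    aln = _get_aligner().align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(a, b))
    return matches / len(a)


def detect_tandem(
    loci: list[GeneLocus],
    sequences: dict[str, str],
    min_similarity: float = DEFAULT_MIN_IDENTITY,
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    all_loci: list[GeneLocus] | None = None,
) -> list[TandemPair]:
    """Adjacent, highly similar same-chromosome pairs.

    ``sequences`` maps gene id → protein (or CDS) sequence; missing
    sequences for placed family loci are an error.  Intervening genes
    are counted over ``all_loci`` when given (e.g. the full annotation),
    otherwise over the family loci themselves.
    """
    placed = [l for l in loci if l.placed]
    missing = sorted(l.gene_id for l in placed if l.gene_id not in sequences)
    if missing:
        raise ValueError(f"missing sequences for loci: {missing}")
    universe = all_loci if all_loci is not None else loci
    pairs = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in placed:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in sorted(by_chrom, key=_natural_key):
        members = sorted(by_chrom[chrom], key=lambda l: l.start)
        between = sorted(
            (u for u in universe if u.placed and u.chromosome == chrom),
            key=lambda l: l.start,
        )
        fam_ids = {l.gene_id for l in members}
        # only consecutive family members qualify as adjacent
        for a, b in zip(members, members[1:]):
            inter = sum(
                1
                for u in between
                if u.gene_id not in (a.gene_id, b.gene_id)
                and u.gene_id not in fam_ids
                and a.end <= u.start and u.end <= b.start
            )
            if inter <= max_intervening:
                ident = alignment_identity(
                    sequences[a.gene_id], sequences[b.gene_id]
                )
                if ident >= min_similarity:
                    pairs.append(TandemPair(a.gene_id, b.gene_id, ident, inter))
    return pairs

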