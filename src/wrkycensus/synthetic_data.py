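"""Synthetic proteomes, genomes and expression matrices with ground truth.

Every downstream stage of the census needs a desk-scale recovery test.
This module plants the exact signals those stages detect:

* proteins carrying WRKY domains with each group's signature
  (group I: two C2H2 domains; IIa/IIb/IId/IIe: C-X5-C-X23-H-X-H;
  IIc: C-X4-C-X23-H-X-H; III/IV: C-X7-C-X23-H-X-C), plus decoys with
  no core heptapeptide and optional planted named motifs;
* GFF3 gene models with planted gene clusters, tandem-duplicate pairs
  and R-/V-type domain introns at the exact junctions the structure
  stage classifies;
* expression matrices with planted expressed-tissue sets, developmental
  trends and treatment responses, with optional log-normal noise.

All generators are seeded and byte-deterministic.  Subgroup prototypes
(IIa/IIb/IId/IIe, and III vs IV) are fixed, mutually divergent domain
sequences, so reference-tree placement can separate what zinc-finger
spacing alone cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .domain_scan import (
    DEFAULT_VARIANTS,
    CANONICAL_CORE,
    ProteinRecord,
)

GROUPS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV")

#: residues safe for flanks/spacers: no C/H (keeps zinc-finger parses
#: unambiguous) and no W (cannot seed a spurious core heptapeptide)
_SAFE = "ADEFGIKLMNPQRSTVY"
_ALL20 = "ACDEFGHIKLMNPQRSTVWY"

#: finger geometry per group: (m, n, terminal residue)
_GEOMETRY = {
    "I": ((4, 22, "H"), (4, 23, "H")),  # two domains
    "IIa": ((5, 23, "H"),),
    "IIb": ((5, 23, "H"),),
    "IIc": ((4, 23, "H"),),
    "IId": ((5, 23, "H"),),
    "IIe": ((5, 23, "H"),),
    "III": ((7, 23, "C"),),
    "IV": ((7, 23, "C"),),
}

#: named motif exemplar sequences (no W/C/H except where intrinsic)
MOTIF_SEQUENCES = {
    "HARF": "RTGHARFRRAP",
    "LxxLL": "LKELL",
    "LxLxLx": "LALALA",
    "leucine_zipper": "LAAKEGALSSREGALTEAKGAL",  # L at heptad positions 0/7/14/21
}

#: single deterministic codon per amino acid (reverse translation)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_LINKER_LEN = 9


# --------------------------------------------------------------------------
# truth records


@dataclass
class ProteinTruth:
    group: str               # group label or "decoy"
    domain_spans: list[tuple[int, int]]
    core_variant: str | None
    motifs: list[str]
    finger_c2: list[int]     # second-Cys protein positions, per domain


@dataclass
class GeneTruth:
    chromosome: str
    start: int
    end: int
    strand: str
    cluster_id: int | None
    tandem_pair_id: int | None
    splice_types: list[str]
    protein: str
    domain_span: tuple[int, int] | None
    finger_c2: int | None


@dataclass
class ExpressionTruth:
    expressed_tissues: list[str]
    trend: str
    responses: dict[str, str]   # "treatment:stage" -> label


@dataclass
class TruthSet:
    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    expression: dict[str, ExpressionTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True, default=list)


# --------------------------------------------------------------------------
# protein generation


@dataclass
class FamilySpec:
    """Composition of a synthetic WRKY family."""

    n_per_group: dict[str, int]
    n_decoys: int = 0
    flank_length_range: tuple[int, int] = (25, 45)
    motif_plants: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if any(v < 0 for v in self.n_per_group.values()) or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.flank_length_range
        if lo > hi or lo < 5:
            raise ValueError("invalid flank length range (min 5, min <= max)")
        if sum(self.n_per_group.values()) + self.n_decoys == 0:
            raise ValueError("empty spec")


def _prototype_rng(group: str) -> np.random.Generator:
    # prototypes are fixed per group, independent of the user seed
    return np.random.default_rng(10_000 + GROUPS.index(group))


def _draw(rng, alphabet: str, k: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=k))


def _domain_template(group: str, geometry: tuple[int, int, str], rng) -> str:
    """Core + linker + zinc finger with group-specific filler residues."""
    m, n, term = geometry
    linker = _draw(rng, _SAFE, _LINKER_LEN)
    sp_m = _draw(rng, _SAFE, m)
    sp_n = list(_draw(rng, _SAFE, n))
    if group in ("IIa", "IIb"):
        sp_n[5] = "V"   # valine six residues after the second cysteine
    x = _draw(rng, _SAFE, 1)
    return CANONICAL_CORE + linker + "C" + sp_m + "C" + "".join(sp_n) + "H" + x + term


def group_prototypes() -> dict[str, list[str]]:
    """Fixed, mutually divergent domain prototypes per group."""
    out = {}
    for group in GROUPS:
        rng = _prototype_rng(group)
        out[group] = [_domain_template(group, g, rng) for g in _GEOMETRY[group]]
    return out


_PROTOTYPES = group_prototypes()


def _domain_layout(domain: str, offset: int) -> tuple[tuple[int, int], int]:
    """(span, second-Cys position) of a planted template at ``offset``.

    Templates are built as core(7) + linker + C-Xm-C-Xn-H-X-[H|C], so the
    first cysteine always sits at 7 + linker length.
    """
    c1 = 7 + _LINKER_LEN
    m = _GEOMETRY_BY_TEMPLATE[domain][0]
    c2 = c1 + m + 1
    return (offset, offset + len(domain)), offset + c2


_GEOMETRY_BY_TEMPLATE = {
    t: g for group in GROUPS for t, g in zip(_PROTOTYPES[group], _GEOMETRY[group])
}


def _mutate_domain(domain: str, rng, n_sub: int) -> str:
    """Substitute filler positions only (never core, C/H anchors or the
    IIa/IIb valine)."""
    geometry = _GEOMETRY_BY_TEMPLATE[domain]
    m = geometry[0]
    c1 = 7 + _LINKER_LEN
    c2 = c1 + m + 1
    protected = set(range(7)) | {
        c1, c2, c2 + 6, len(domain) - 3, len(domain) - 2, len(domain) - 1
    }
    mutable = [i for i in range(7, len(domain)) if i not in protected]
    chars = list(domain)
    for pos in rng.choice(mutable, size=min(n_sub, len(mutable)), replace=False):
        chars[pos] = _SAFE[rng.integers(0, len(_SAFE))]
    return "".join(chars)


def _clean_flank(rng, length: int) -> str:
    """i.i.d. uniform flank, rejection-sampled against core variants."""
    while True:
        flank = _draw(rng, _ALL20, length)
        if not any(v in flank for v in DEFAULT_VARIANTS):
            return flank


def _plant_motif(flank: str, motif: str) -> str:
    if len(flank) < len(motif) + 2:
        flank = flank + flank
    pos = 1
    return flank[:pos] + motif + flank[pos + len(motif):]


def make_protein(
    group: str,
    index: int,
    rng,
    flank_range: tuple[int, int],
    motifs: list[str] | None = None,
    long_protein: bool = False,
    n_mutations: int = 2,
    core_variant: str = CANONICAL_CORE,
) -> tuple[ProteinRecord, ProteinTruth]:
    """One synthetic family member with exact domain-span truth."""
    templates = [
        _mutate_domain(t, rng, int(rng.integers(0, n_mutations + 1)))
        for t in _PROTOTYPES[group]
    ]
    if core_variant != CANONICAL_CORE:
        templates = [core_variant + t[7:] for t in templates]
    lo, hi = flank_range
    nflank = _clean_flank(rng, int(rng.integers(lo, hi + 1)))
    for motif in motifs or []:
        nflank = _plant_motif(nflank, MOTIF_SEQUENCES[motif])
    parts = [nflank]
    spans, c2s = [], []
    offset = len(nflank)
    for k, tpl in enumerate(templates):
        (span, c2) = _domain_layout(_PROTOTYPES[group][k], offset)
        spans.append(span)
        c2s.append(c2)
        parts.append(tpl)
        offset += len(tpl)
        if k < len(templates) - 1:
            inter = _clean_flank(rng, int(rng.integers(lo, hi + 1)))
            parts.append(inter)
            offset += len(inter)
    cflank = _clean_flank(rng, int(rng.integers(lo, hi + 1)))
    parts.append(cflank)
    if long_protein or group == "IV":
        # group-IV analogs are far longer than typical family members
        pad = _clean_flank(rng, 900)
        parts.append(pad)
    sequence = "".join(parts)
    pid = f"SYN_{group}_{index:02d}"
    record = ProteinRecord(pid, sequence, gene_id=pid)
    truth = ProteinTruth(
        group=group,
        domain_spans=spans,
        core_variant=core_variant,
        motifs=sorted(motifs or []),
        finger_c2=c2s,
    )
    return record, truth


def make_decoy(index: int, rng, length_range=(150, 400)) -> tuple[ProteinRecord, ProteinTruth]:
    length = int(rng.integers(*length_range))
    seq = _clean_flank(rng, length)
    pid = f"SYN_decoy_{index:02d}"
    return ProteinRecord(pid, seq, gene_id=pid), ProteinTruth(
        group="decoy", domain_spans=[], core_variant=None, motifs=[], finger_c2=[]
    )


def gen_proteins(spec: FamilySpec) -> tuple[list[ProteinRecord], TruthSet]:
    """Generate the synthetic family described by ``spec``.

    Emission order: groups in canonical order, then decoys; the indices
    in ``spec.motif_plants`` refer to this order.
    """
    rng = np.random.default_rng(spec.seed)
    records, truth = [], TruthSet()
    plants_by_index: dict[int, list[str]] = {}
    for motif, targets in spec.motif_plants.items():
        if motif not in MOTIF_SEQUENCES:
            raise ValueError(f"unknown motif {motif!r}")
        for t in targets:
            plants_by_index.setdefault(t, []).append(motif)
    emit_idx = 0
    for group in GROUPS:
        for k in range(spec.n_per_group.get(group, 0)):
            motifs = plants_by_index.get(emit_idx, [])
            rec, pt = make_protein(
                group, k + 1, rng, spec.flank_length_range, motifs=motifs
            )
            records.append(rec)
            truth.proteins[rec.id] = pt
            emit_idx += 1
    for k in range(spec.n_decoys):
        rec, pt = make_decoy(k + 1, rng)
        records.append(rec)
        truth.proteins[rec.id] = pt
        emit_idx += 1
    return records, truth


def reference_set(seed: int = 424242) -> tuple[dict[str, str], dict[str, str]]:
    """Labelled reference domain sequences, one exemplar per subgroup.

    Returns (domain sequences by reference id, labels by reference id).
    Mirrors using a model-plant reference family for placement.
    """
    rng = np.random.default_rng(seed)
    domains, labels = {}, {}
    for group in ("IIa", "IIb", "IIc", "IId", "IIe", "III"):
        # several group-III exemplars so the clade they span is well
        # defined; one exemplar suffices for the II subgroups
        n_ex = 3 if group == "III" else 1
        for k in range(1, n_ex + 1):
            tpl = _mutate_domain(_PROTOTYPES[group][0], rng, 1)
            rid = f"REF_{group}" if k == 1 else f"REF_{group}_{k}"
            domains[rid] = tpl
            labels[rid] = group
    return domains, labels


# --------------------------------------------------------------------------
# genome generation


_GENE_SPACING = 250_000   # keeps unrelated neighbours out of cluster range
_TANDEM_GAP = 2_000


def _reverse_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein) + "TAA"


@dataclass
class _PlannedGene:
    gene_id: str
    protein: str
    splice_plan: list[str]
    domain_span: tuple[int, int] | None
    finger_c2: int | None
    cluster_id: int | None = None
    tandem_pair_id: int | None = None


def _split_points(gene: _PlannedGene) -> list[int]:
    """Coding-nucleotide offsets where introns are inserted (sorted)."""
    pts = []
    span, c2 = gene.domain_span, gene.finger_c2
    core_start = span[0] if span else None
    for stype in gene.splice_plan:
        if stype == "R":
            pts.append(3 * (core_start + 1))        # before the core arginine
        elif stype == "V":
            pts.append(3 * (c2 + 6))                # before the finger valine
        elif stype == "other":
            pts.append(3 * (core_start + 3))        # before the core tyrosine
        elif stype == "none":
            pts.append(6)                           # inside the N-flank
        else:
            raise ValueError(f"unknown splice type {stype!r}")
    return sorted(set(pts))


def gen_genome(
    n_genes: int,
    n_chromosomes: int,
    cluster_plan: list[tuple[str, int, int]] | None = None,
    tandem_pairs: int = 0,
    intron_plan: dict[int, list[str]] | None = None,
    seed: int = 0,
    chromosome_size: int = 1_000_000,
    cluster_threshold: int = 200_000,
    _planned: list[_PlannedGene] | None = None,
) -> tuple[str, TruthSet]:
    """Emit GFF3 text plus ground truth for clusters/tandems/introns.

    ``cluster_plan`` entries are (chromosome, member count, span bp) and
    must fit under the downstream cluster threshold; ``intron_plan``
    maps gene index -> list of splice types to plant.  Gene content is
    WRKY-like for genes with planted domain introns and decoy-like
    otherwise; a fully specified gene list can be supplied instead via
    the private hook used by the bundle generator.
    """
    rng = np.random.default_rng(seed)
    cluster_plan = cluster_plan or []
    intron_plan = intron_plan or {}

    if _planned is None:
        _planned = []
        for i in range(n_genes):
            plan = intron_plan.get(i, [])
            if any(s in ("R", "V", "other") for s in plan):
                group = "IIb" if "V" in plan else "IIc"
                rec, pt = make_protein(group, i + 1, rng, (25, 40))
                _planned.append(
                    _PlannedGene(
                        f"SYNGENE_{i + 1:03d}", rec.sequence, plan,
                        pt.domain_spans[0], pt.finger_c2[0],
                    )
                )
            else:
                rec, _ = make_decoy(i + 1, rng, (120, 250))
                _planned.append(
                    _PlannedGene(f"SYNGENE_{i + 1:03d}", rec.sequence, plan, None, None)
                )
    genes = list(_planned)

    # tandem pairs: duplicate existing genes with two-residue divergence
    pair_id = 0
    for _ in range(tandem_pairs):
        candidates = [g for g in genes if g.tandem_pair_id is None]
        if not candidates:
            raise ValueError("infeasible packing: no genes left for tandem pairs")
        pair_id += 1
        src = candidates[int(rng.integers(0, len(candidates)))]
        prot = list(src.protein)
        span = src.domain_span
        for _ in range(2):
            while True:
                p = int(rng.integers(0, len(prot)))
                if span and span[0] <= p < span[1]:
                    continue
                break
            prot[p] = _SAFE[int(rng.integers(0, len(_SAFE)))]
        dup = _PlannedGene(
            f"{src.gene_id}_td{pair_id}", "".join(prot), list(src.splice_plan),
            src.domain_span, src.finger_c2, tandem_pair_id=pair_id,
        )
        src.tandem_pair_id = pair_id
        genes.append(dup)

    if n_genes == 0 and not genes:
        gff = "##gff-version 3\n"
        return gff, TruthSet()

    # ---- placement
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    cursor = {c: 10_000 for c in chroms}
    placements: list[tuple[_PlannedGene, str, int]] = []  # gene, chrom, start
    unplaced = [g for g in genes if g.tandem_pair_id is None]

    cluster_id = 0
    for chrom, count, span_bp in cluster_plan:
        cluster_id += 1
        if chrom not in cursor:
            raise ValueError(
                f"infeasible packing: unknown chromosome in {(chrom, count, span_bp)}"
            )
        if count > 1 and span_bp / (count - 1) > cluster_threshold:
            raise ValueError(
                f"infeasible packing: span too wide for threshold in {(chrom, count, span_bp)}"
            )
        if count > len(unplaced):
            raise ValueError(f"infeasible packing: not enough genes for {(chrom, count, span_bp)}")
        step = span_bp // max(count - 1, 1)
        base = cursor[chrom]
        for k in range(count):
            g = unplaced.pop(0)
            g.cluster_id = cluster_id
            placements.append((g, chrom, base + k * step))
        cursor[chrom] = base + span_bp + _GENE_SPACING

    # tandem pairs: adjacent placement; each pair is also a tight cluster
    pairs: dict[int, list[_PlannedGene]] = {}
    for g in genes:
        if g.tandem_pair_id is not None:
            pairs.setdefault(g.tandem_pair_id, []).append(g)
    for pid_, members in sorted(pairs.items()):
        chrom = chroms[(pid_ - 1) % len(chroms)]
        base = cursor[chrom]
        offset = 0
        cluster_id += 1
        for g in members:
            g.cluster_id = cluster_id
            placements.append((g, chrom, base + offset))
            offset += len(_reverse_translate(g.protein)) + 400 * len(g.splice_plan) + _TANDEM_GAP
        cursor[chrom] = base + offset + _GENE_SPACING

    ci = 0
    while unplaced:
        g = unplaced.pop(0)
        chrom = chroms[ci % len(chroms)]
        ci += 1
        placements.append((g, chrom, cursor[chrom]))
        cursor[chrom] += _GENE_SPACING

    for chrom, pos in cursor.items():
        if pos > chromosome_size:
            raise ValueError(
                f"infeasible packing: {chrom} needs {pos} bp > {chromosome_size}"
            )

    # ---- feature construction
    lines = ["##gff-version 3"]
    for c in chroms:
        lines.append(f"##sequence-region {c} 1 {chromosome_size}")
    truth = TruthSet()
    features = []
    for g, chrom, start in placements:
        cds_nt = _reverse_translate(g.protein)
        pts = _split_points(g)
        segments = []
        prev = 0
        for p in pts:
            segments.append(cds_nt[prev:p])
            prev = p
        segments.append(cds_nt[prev:])
        segments = [s for s in segments if s]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        intron_len = 300
        # genomic layout in transcription order
        tx_coords = []
        pos = 0
        for s in segments:
            tx_coords.append((pos, pos + len(s)))
            pos += len(s) + intron_len
        total_span = pos - intron_len
        if strand == "+":
            genomic = [(start + a, start + b) for a, b in tx_coords]
        else:
            genomic = [(start + total_span - b, start + total_span - a) for a, b in tx_coords]
        end = start + total_span
        gid = g.gene_id
        features.append((chrom, start, end, strand, gid, sorted(genomic)))
        truth.genes[gid] = GeneTruth(
            chromosome=chrom,
            start=start,
            end=end,
            strand=strand,
            cluster_id=g.cluster_id,
            tandem_pair_id=g.tandem_pair_id,
            splice_types=_ordered_types(g, pts),
            protein=g.protein,
            domain_span=g.domain_span,
            finger_c2=g.finger_c2,
        )

    for chrom, start, end, strand, gid, genomic in sorted(
        features, key=lambda f: (_natural(f[0]), f[1])
    ):
        lines.append(
            f"{chrom}\twrkycensus\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        mid = f"{gid}.m1"
        lines.append(
            f"{chrom}\twrkycensus\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\tID={mid};Parent={gid}"
        )
        for k, (a, b) in enumerate(genomic, 1):
            lines.append(
                f"{chrom}\twrkycensus\texon\t{a + 1}\t{b}\t.\t{strand}\t.\tID={mid}.exon{k};Parent={mid}"
            )
            lines.append(
                f"{chrom}\twrkycensus\tCDS\t{a + 1}\t{b}\t.\t{strand}\t.\tID={mid}.cds{k};Parent={mid}"
            )
    return "\n".join(lines) + "\n", truth


def _natural(chrom: str):
    import re

    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", chrom))


def _ordered_types(gene: _PlannedGene, pts: list[int]) -> list[str]:
    type_by_point = {}
    span, c2 = gene.domain_span, gene.finger_c2
    core_start = span[0] if span else None
    for stype in gene.splice_plan:
        if stype == "R":
            type_by_point[3 * (core_start + 1)] = "R"
        elif stype == "V":
            type_by_point[3 * (c2 + 6)] = "V"
        elif stype == "other":
            type_by_point[3 * (core_start + 3)] = "other"
        elif stype == "none":
            type_by_point[6] = "none"
    return [type_by_point[p] for p in pts]


# --------------------------------------------------------------------------
# expression generation


DEFAULT_TISSUES = ("root", "stem", "leaf", "fruit")
DEFAULT_STAGES = (18, 24, 30, 36, 42)
DEFAULT_TREATMENTS = ("IAA", "ABA", "sucrose")

_BASE_LEVEL = 10.0
_TREND_FOLD = 16.0
_RESPONSE_FOLD = 8.0


@dataclass
class ExpressionPlan:
    expressed_tissues: tuple[str, ...]
    trend: str                      # up | down | flat
    responses: dict[tuple[str, int], str]


def default_expression_plan(
    gene_ids: list[str],
    tissues=DEFAULT_TISSUES,
    stages=DEFAULT_STAGES,
    treatments=DEFAULT_TREATMENTS,
    seed: int = 0,
) -> dict[str, ExpressionPlan]:
    """A mixed, deterministic assignment of planted labels."""
    rng = np.random.default_rng(seed)
    trends = ("up", "down", "flat")
    resp = ("induced", "repressed", "unchanged", "undetected")
    tsets = (
        tuple(tissues),
        ("root",),
        ("fruit",),
        ("root", "fruit"),
        (),
        ("leaf", "fruit"),
    )
    plans = {}
    for i, gid in enumerate(gene_ids):
        tset = tsets[i % len(tsets)]
        trend = trends[i % 3] if "fruit" in tset else "flat"
        responses = {}
        for j, tr in enumerate(treatments):
            for k, st in enumerate((stages[0], stages[-2] if len(stages) > 1 else stages[0])):
                responses[(tr, st)] = (
                    resp[(i + j + k) % 4] if "fruit" in tset else "undetected"
                )
        plans[gid] = ExpressionPlan(tset, trend, responses)
    return plans


def gen_expression(
    gene_ids: list[str],
    tissues=DEFAULT_TISSUES,
    stages=DEFAULT_STAGES,
    treatments=DEFAULT_TREATMENTS,
    planted: dict[str, ExpressionPlan] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Expression matrix + sample metadata + truth.

    Values are linear-scale abundances; noise is additive Gaussian on
    the log2 scale (zero entries stay zero).  Planted folds (16 across
    stages, 8 for treatment responses) must exceed the downstream fold
    threshold of 2 by at least two noise standard deviations.
    """
    if list(stages) != sorted(set(stages)):
        raise ValueError("stages must be strictly increasing")
    if noise_sd < 0 or 2.0 * noise_sd > np.log2(_RESPONSE_FOLD / 2.0):
        raise ValueError("noise_sd too large for the planted fold changes")
    if planted is None:
        planted = default_expression_plan(gene_ids, tissues, stages, treatments)
    rng = np.random.default_rng(seed)

    columns: list[str] = []
    meta_rows: list[dict] = []
    for t in tissues:
        columns.append(t)
        meta_rows.append({"sample": t, "tissue": t, "stage": "", "treatment": "none", "control_pair": ""})
    for s in stages:
        col = f"Day{s}"
        columns.append(col)
        meta_rows.append({"sample": col, "tissue": "fruit", "stage": s, "treatment": "none", "control_pair": ""})
    treat_stages = (stages[0], stages[-2] if len(stages) > 1 else stages[0])
    for tr in treatments:
        for s in treat_stages:
            ck = f"{tr}.CK.{s}d"
            tcol = f"{tr}.{s}d"
            columns += [ck, tcol]
            meta_rows.append({"sample": ck, "tissue": "fruit", "stage": s, "treatment": "none", "control_pair": ""})
            meta_rows.append({"sample": tcol, "tissue": "fruit", "stage": s, "treatment": tr, "control_pair": ck})

    k = len(stages)
    ratio = _TREND_FOLD ** (1.0 / (k - 1)) if k > 1 else 1.0
    data = np.zeros((len(gene_ids), len(columns)))
    truth = TruthSet()
    col_idx = {c: i for i, c in enumerate(columns)}
    for gi, gid in enumerate(gene_ids):
        plan = planted[gid]
        for t in tissues:
            if t in plan.expressed_tissues:
                data[gi, col_idx[t]] = _BASE_LEVEL
        if "fruit" in plan.expressed_tissues:
            for si, s in enumerate(stages):
                if plan.trend == "up":
                    v = _BASE_LEVEL * ratio ** si
                elif plan.trend == "down":
                    v = _BASE_LEVEL * ratio ** (k - 1 - si)
                else:
                    v = _BASE_LEVEL
                data[gi, col_idx[f"Day{s}"]] = v
        for (tr, s), label in plan.responses.items():
            ck, tcol = f"{tr}.CK.{s}d", f"{tr}.{s}d"
            if label == "undetected":
                cv = tv = 0.0
            elif label == "induced":
                cv, tv = _BASE_LEVEL, _BASE_LEVEL * _RESPONSE_FOLD
            elif label == "repressed":
                cv, tv = _BASE_LEVEL, _BASE_LEVEL / _RESPONSE_FOLD
            else:
                cv = tv = _BASE_LEVEL
            data[gi, col_idx[ck]] = cv
            data[gi, col_idx[tcol]] = tv
        truth.expression[gid] = ExpressionTruth(
            expressed_tissues=sorted(plan.expressed_tissues),
            trend=plan.trend,
            responses={f"{tr}:{s}": lab for (tr, s), lab in plan.responses.items()},
        )

    if noise_sd > 0:
        mask = data > 0
        noise = rng.normal(0.0, noise_sd, size=data.shape)
        data = np.where(mask, np.maximum(data * 2.0 ** noise, 0.0), 0.0)

    values = pd.DataFrame(data, index=list(gene_ids), columns=columns)
    metadata = pd.DataFrame(meta_rows)
    return values, metadata, truth

# --------------------------------------------------------------------------
# coherent bundle (proteome + genome + expression over the same gene ids)


def simulate_bundle(
    spec: FamilySpec,
    outdir: str,
    n_chromosomes: int = 7,
    cluster_plan: list[tuple[str, int, int]] | None = None,
    tandem_pairs: int = 1,
    noise_sd: float = 0.0,
    chromosome_size: int = 2_000_000,
) -> tuple[dict[str, str], TruthSet]:
    """Write a coherent census input bundle to ``outdir``.

    The same gene identifiers thread through the protein FASTA, the
    GFF3 gene models and the expression matrix, so the full pipeline
    can run end to end against one truth document.  Returns a mapping
    of artifact names to file paths plus the merged truth.
    """
    import os

    from .io import write_fasta

    if cluster_plan is None:
        cluster_plan = [("chr1", 2, 150_000)]
    records, ptruth = gen_proteins(spec)

    planned = []
    for rec in records:
        pt = ptruth.proteins[rec.id]
        if pt.group == "decoy":
            plan = ["none"]
        elif pt.group in ("IIa", "IIb"):
            plan = ["V"]
        else:
            plan = ["R"]
        span = pt.domain_spans[-1] if pt.domain_spans else None
        c2 = pt.finger_c2[-1] if pt.finger_c2 else None
        planned.append(_PlannedGene(rec.id, rec.sequence, plan, span, c2))

    gff, gtruth = gen_genome(
        n_genes=len(planned),
        n_chromosomes=n_chromosomes,
        cluster_plan=cluster_plan,
        tandem_pairs=tandem_pairs,
        seed=spec.seed + 1,
        chromosome_size=chromosome_size,
        _planned=planned,
    )

    # tandem duplicates are new proteome members: same group as source
    all_records = list(records)
    for gid, gt in gtruth.genes.items():
        if gid not in ptruth.proteins:
            src_id = gid.rsplit("_td", 1)[0]
            src = ptruth.proteins[src_id]
            all_records.append(ProteinRecord(gid, gt.protein, gene_id=gid))
            ptruth.proteins[gid] = ProteinTruth(
                group=src.group,
                domain_spans=list(src.domain_spans),
                core_variant=src.core_variant,
                motifs=[],
                finger_c2=list(src.finger_c2),
            )

    gene_ids = [r.id for r in all_records]
    values, metadata, etruth = gen_expression(
        gene_ids, noise_sd=noise_sd, seed=spec.seed + 2
    )

    truth = TruthSet(
        proteins=ptruth.proteins, genes=gtruth.genes, expression=etruth.expression
    )

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "proteins": os.path.join(outdir, "proteins.faa"),
        "genome": os.path.join(outdir, "genome.gff3"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(all_records, paths["proteins"])
    with open(paths["genome"], "w") as fh:
        fh.write(gff)
    values.to_csv(paths["expression"], sep="\t", index_label="gene")
    metadata.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths, truth
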