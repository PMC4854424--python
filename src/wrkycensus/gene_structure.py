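"""Exon–intron organization derived from GFF3 gene models.

Builds one model per gene (longest mRNA by coding length), derives
introns between consecutive CDS segments in transcription order, their
phases (cumulative upstream coding length mod 3), and — for introns
falling inside a WRKY domain — their splice type:

* R-type: spliced immediately before a conserved arginine codon;
* V-type: spliced before a valine located exactly six residues after
  the second cysteine of the zinc finger (seen in subgroups IIa/IIb);
* other inside-domain introns are labelled ``other``; introns outside
  the domain ``none``.

Coordinates are converted from GFF3 (1-based inclusive) to 0-based
half-open; minus-strand models are ordered 5'→3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

from .domain_scan import WRKYDomain

logger = logging.getLogger(__name__)

SPLICE_TYPES = ("R", "V", "other", "none")


@dataclass
class GeneModel:
    """Strand-aware exon/CDS layout of one gene (one chosen isoform)."""

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]          # genomic, 0-based half-open
    cds: list[tuple[int, int]]            # transcription order
    mrna_id: str | None = None

    def __post_init__(self) -> None:
        total = sum(e - s for s, e in self.cds)
        if total % 3:
            logger.warning(
                "gene %s: CDS length %d not divisible by 3", self.gene_id, total
            )

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive CDS, transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if self.strand == "+":
                out.append((e1, s2))
            else:
                out.append((e2, s1))
        return out

    @property
    def n_introns(self) -> int:
        return len(self.cds) - 1

    def upstream_cds_lengths(self) -> list[int]:
        """Coding nucleotides 5' of each intron."""
        out, total = [], 0
        for s, e in self.cds[:-1]:
            total += e - s
            out.append(total)
        return out


@dataclass
class IntronAnnotation:
    index: int
    phase: int
    in_domain: bool
    splice_type: str

    def __post_init__(self):
        if self.splice_type not in SPLICE_TYPES:
            raise ValueError(f"unknown splice type {self.splice_type!r}")
        if not self.in_domain and self.splice_type not in ("other", "none"):
            raise ValueError("splice types R/V require in_domain")


def build_models(gff3_path: str) -> list[GeneModel]:
    """Parse GFF3 into one GeneModel per gene (longest mRNA by CDS)."""
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes:
            raise ValueError(f"CDS without Parent at {cds.seqid}:{cds.start}")
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            exons = list(db.children(mrna, featuretype="exon", order_by="start"))
            if not cds:
                continue
            total = sum(c.end - c.start + 1 for c in cds)
            if best is None or total > best[0]:
                best = (total, mrna, cds, exons)
        if best is None:
            logger.warning("gene %s has no coding mRNA; skipped", gene.id)
            continue
        _, mrna, cds, exons = best
        intervals = sorted((c.start - 1, c.end) for c in cds)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS in mRNA {mrna.id}")
        if gene.strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                exons=sorted((e.start - 1, e.end) for e in exons),
                cds=intervals,
                mrna_id=mrna.id,
            )
        )
    return models


def intron_phases(model: GeneModel) -> list[int]:
    """Phase of each intron: upstream coding length mod 3."""
    return [u % 3 for u in model.upstream_cds_lengths()]


def classify_domain_introns(
    model: GeneModel,
    protein_sequence: str,
    domain: WRKYDomain | None,
    v_position_tolerance: int = 0,
) -> list[IntronAnnotation]:
    """Type every intron of the model against one WRKY domain.

    The residue "immediately 3' of the junction" is the residue whose
    codon contains the first coding nucleotide after the intron, making
    the typing total for phase-1/2 introns as well.  V-type calls
    additionally require the valine to sit exactly six residues after
    the finger's second cysteine (±``v_position_tolerance``).
    """
    phases = intron_phases(model)
    span = domain.span if domain is not None else None
    if span is not None and span[1] > len(protein_sequence):
        raise ValueError("domain span beyond protein length")
    out = []
    for i, upstream in enumerate(model.upstream_cds_lengths()):
        residue_idx = upstream // 3
        in_domain = span is not None and span[0] <= residue_idx < span[1]
        if not in_domain:
            stype = "none"
        else:
            residue = (
                protein_sequence[residue_idx]
                if residue_idx < len(protein_sequence)
                else ""
            )
            if residue == "R":
                stype = "R"
            elif residue == "V" and domain.finger is not None and (
                abs(residue_idx - (domain.finger.c2 + 6)) <= v_position_tolerance
            ):
                stype = "V"
            else:
                stype = "other"
        out.append(IntronAnnotation(i, phases[i], in_domain, stype))
    return out
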