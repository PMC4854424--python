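"""Full-census orchestration: scan → classify → profile → structure →
map → tree → expression, from one configuration.

Produces the census table (one row per family member: name, gene id,
chromosome, ORF length, MW, pI, aliphatic index, GRAVY, instability,
core-motif count or variant, domain pattern, group, zinc finger), a
group-size summary, and a manifest of every artifact written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import (
    classify,
    domain_scan,
    expression as expr_mod,
    gene_structure,
    genome_map,
    io as fio,
    phylogeny,
)

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV", "NG", "total")


@dataclass
class CensusConfig:
    """Inputs and thresholds for one census run."""

    fasta: str
    gff3: str | None = None
    references: str | None = None          # labelled reference FASTA
    reference_labels: dict[str, str] = field(default_factory=dict)
    expression_matrix: str | None = None
    expression_metadata: str | None = None
    name_prefix: str = "FvWRKY"
    cluster_gap: int = genome_map.DEFAULT_CLUSTER_GAP
    min_similarity: float = genome_map.DEFAULT_MIN_IDENTITY
    max_intervening: int = genome_map.DEFAULT_MAX_INTERVENING
    divergence_length: int = classify.DEFAULT_DIVERGENCE_LENGTH
    expressed_threshold: float = 0.0
    fold_threshold: float = 2.0
    bootstrap_replicates: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "CensusConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def summarize_groups(census: pd.DataFrame) -> pd.Series:
    """Counts per group (IV and NG separate, plus an NG+IV merge).

    The merged column mirrors summary tables that fold highly divergent
    members into a single no-group bucket.
    """
    counts = {g: 0 for g in SUMMARY_COLUMNS}
    for g in census["group"]:
        counts[g] = counts.get(g, 0) + 1
    counts["total"] = len(census)
    out = pd.Series(counts)
    out["NG+IV"] = out["NG"] + out["IV"]
    return out


def _census_rows(
    annotations: list[classify.FamilyAnnotation],
    loci_by_gene: dict[str, "genome_map.GeneLocus"],
) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        locus = loci_by_gene.get(ann.protein_id)
        n_core = sum(1 for d in ann.domains if d.complete)
        variants = {d.core.peptide for d in ann.domains if not d.core.canonical}
        rows.append(
            {
                "name": locus.name if locus else ann.protein_id,
                "gene_id": ann.protein_id,
                "chr": locus.chromosome if locus else "unplaced",
                "ORF_aa": ann.physchem.length,
                "MW_kDa": round(ann.physchem.mw / 1000.0, 4),
                "pI": ann.physchem.pi,
                "Ai": round(ann.physchem.ai, 2),
                "GRAVY": round(ann.physchem.gravy, 3),
                "instability": round(ann.physchem.instability, 2),
                "core_motifs": n_core if not variants else ",".join(sorted(variants)),
                "domain_pattern": ";".join(ann.pattern_strings),
                "group": ann.group.value,
                "zinc_finger": ";".join(
                    d.finger.finger_class for d in ann.domains if d.complete
                ),
                "harf": ann.motifs.harf,
                "lxxll": ann.motifs.lxxll,
                "lxlxlx": ann.motifs.lxlxlx,
                "leucine_zipper": ann.motifs.leucine_zipper,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("name").reset_index(drop=True)
    return df


def run_census(config: CensusConfig, outdir: str) -> dict:
    """Execute the full census; returns a result dict with dataframes.

    Optional stages (gene structure, mapping, tree, expression) degrade
    gracefully when their inputs are absent.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    result: dict = {}

    proteins = fio.read_fasta(config.fasta)
    if not proteins:
        raise ValueError("empty FASTA input")
    domains = domain_scan.scan_proteome(proteins)
    positive = {pid for pid, doms in domains.items() if doms}

    # ---- phylogeny + classification
    tree = None
    labels = None
    if config.references:
        refs = fio.read_fasta(config.references)
        ref_domains = {}
        labels = {}
        for rec in refs:
            scanned = domain_scan.scan_protein(rec)
            comp = domain_scan.complete_domains(scanned)
            if not comp:
                logger.warning("reference %s has no complete domain; skipped", rec.id)
                continue
            s, e = comp[-1].span
            ref_domains[rec.id] = rec.sequence[s:e]
            label = config.reference_labels.get(rec.id)
            if label is None and rec.description:
                label = rec.description.split()[-1]
            labels[rec.id] = label
        query_domains = {}
        for p in proteins:
            comp = domain_scan.complete_domains(domains[p.id])
            if comp:
                s, e = comp[-1].span
                query_domains[p.id] = p.sequence[s:e]
        if len(query_domains) + len(ref_domains) >= 3:
            aln = phylogeny.align_progressive(
                list(query_domains) + list(ref_domains),
                list(query_domains.values()) + list(ref_domains.values()),
            )
            tree = phylogeny.bootstrap(
                aln, replicates=config.bootstrap_replicates, seed=config.seed
            )
            tree_path = os.path.join(outdir, "tree.nwk")
            with open(tree_path, "w") as fh:
                fh.write(tree.to_newick() + "\n")
            written.append(tree_path)
            result["tree"] = tree

    annotations = classify.annotate_family(
        proteins,
        domains,
        tree=tree,
        reference_labels=labels,
        divergence_length=config.divergence_length,
    )
    result["annotations"] = annotations

    # ---- genome map + gene structure
    loci_by_gene: dict[str, genome_map.GeneLocus] = {}
    if config.gff3:
        models = gene_structure.build_models(config.gff3)
        by_id = {p.id: p for p in proteins}
        family_models = [m for m in models if m.gene_id in positive]
        loci = [
            genome_map.GeneLocus(
                m.gene_id, m.chromosome, min(s for s, _ in m.cds),
                max(e for _, e in m.cds), m.strand,
            )
            for m in family_models
        ]
        genome_map.assign_names(loci, prefix=config.name_prefix)
        loci_by_gene = {l.gene_id: l for l in loci}
        clusters = genome_map.detect_clusters(loci, config.cluster_gap)
        sequences = {p.id: p.sequence for p in proteins}
        tandem = genome_map.detect_tandem(
            loci,
            sequences,
            config.min_similarity,
            config.max_intervening,
            all_loci=[
                genome_map.GeneLocus(
                    m.gene_id, m.chromosome, min(s for s, _ in m.cds),
                    max(e for _, e in m.cds), m.strand,
                )
                for m in models
            ],
        )
        result["clusters"] = clusters
        result["tandem"] = tandem

        intron_rows = []
        for m in family_models:
            protein = by_id[m.gene_id]
            comp = domain_scan.complete_domains(domains[m.gene_id])
            domain = comp[-1] if comp else None
            for ann in gene_structure.classify_domain_introns(
                m, protein.sequence, domain
            ):
                intron_rows.append(
                    {
                        "gene_id": m.gene_id,
                        "intron": ann.index,
                        "phase": ann.phase,
                        "in_domain": ann.in_domain,
                        "splice_type": ann.splice_type,
                    }
                )
        introns = pd.DataFrame(intron_rows)
        result["introns"] = introns
        ipath = os.path.join(outdir, "introns.tsv")
        introns.to_csv(ipath, sep="\t", index=False)
        written.append(ipath)

        mpath = os.path.join(outdir, "map.tsv")
        pd.DataFrame(
            [
                {
                    "name": l.name,
                    "gene_id": l.gene_id,
                    "chr": l.chromosome,
                    "start": l.start,
                    "end": l.end,
                    "strand": l.strand,
                }
                for l in loci
            ]
        ).to_csv(mpath, sep="\t", index=False)
        written.append(mpath)

    # ---- census table + summary
    census = _census_rows(annotations, loci_by_gene)
    result["census"] = census
    cpath = os.path.join(outdir, "census.tsv")
    census.to_csv(cpath, sep="\t", index=False)
    written.append(cpath)

    summary = summarize_groups(census)
    result["summary"] = summary
    spath = os.path.join(outdir, "summary.tsv")
    summary.to_frame("count").to_csv(spath, sep="\t", index_label="group")
    written.append(spath)

    # ---- expression
    if config.expression_matrix and config.expression_metadata:
        data = expr_mod.ExpressionData.from_tsv(
            config.expression_matrix, config.expression_metadata
        )
        calls = expr_mod.call_all(
            data, config.expressed_threshold, config.fold_threshold
        )
        result["expression_calls"] = calls
        epath = os.path.join(outdir, "calls.tsv")
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "expressed_tissues": ",".join(sorted(c.expressed_tissues)),
                    "trend": c.trend or "",
                    "responses": ";".join(
                        f"{tr}:{st}={lab}" for (tr, st), lab in sorted(c.responses.items())
                    ),
                }
                for c in calls
            ]
        ).to_csv(epath, sep="\t", index=False)
        written.append(epath)
    else:
        logger.info("expression inputs absent; stage skipped")
        result["expression_calls"] = None

    manifest = {
        os.path.basename(p): hashlib.sha256(open(p, "rb").read()).hexdigest()
        for p in written
    }
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    result["manifest"] = manifest
    return result
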