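"""Run the complete census end to end on a synthetic bundle.

Simulates a proteome, genome and expression matrix sharing one set of
gene identifiers, runs scan -> classify -> profile -> structure -> map
-> tree -> expression, and prints the census table and the group-size
summary.  The summary counts should equal the planted composition.
"""

import tempfile

from wrkycensus.domain_scan import ProteinRecord
from wrkycensus.io import write_fasta
from wrkycensus.report import CensusConfig, run_census
from wrkycensus.synthetic_data import GROUPS, FamilySpec, reference_set, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    spec = FamilySpec(n_per_group={g: 2 for g in GROUPS}, n_decoys=4, seed=7)
    paths, truth = simulate_bundle(spec, f"{tmp}/sim")

    ref_domains, ref_labels = reference_set()
    refs = f"{tmp}/refs.faa"
    write_fasta([ProteinRecord(r, s) for r, s in ref_domains.items()], refs)

    config = CensusConfig(
        fasta=paths["proteins"],
        gff3=paths["genome"],
        references=refs,
        reference_labels=ref_labels,
        expression_matrix=paths["expression"],
        expression_metadata=paths["samples"],
        bootstrap_replicates=50,
        seed=1,
    )
    result = run_census(config, f"{tmp}/out")

    census = result["census"]
    cols = ["name", "gene_id", "chr", "ORF_aa", "MW_kDa", "pI", "group", "domain_pattern"]
    print(census[cols].to_string(index=False))
    print("\nGroup sizes:", result["summary"].to_dict())
    planted = {}
    for t in truth.proteins.values():
        if t.group != "decoy":
            planted[t.group] = planted.get(t.group, 0) + 1
    print("Planted    :", dict(sorted(planted.items())))
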