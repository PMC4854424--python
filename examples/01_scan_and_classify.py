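"""Scan a small synthetic proteome for WRKY domains and classify it.

Generates one protein per family group plus two decoys, runs the
domain scanner and the rule+tree classifier, and prints one line per
protein: the parsed zinc-finger pattern and the recovered group.  With
the planted truth in hand you can see that every label is recovered.
"""

from wrkycensus.classify import annotate_family, build_reference_tree
from wrkycensus.domain_scan import complete_domains, scan_proteome
from wrkycensus.synthetic_data import GROUPS, FamilySpec, gen_proteins, reference_set

spec = FamilySpec(n_per_group={g: 1 for g in GROUPS}, n_decoys=2, seed=11)
records, truth = gen_proteins(spec)
domains = scan_proteome(records)

query_domains = {}
for rec in records:
    comp = complete_domains(domains[rec.id])
    if comp:
        s, e = comp[-1].span
        query_domains[rec.id] = rec.sequence[s:e]

ref_domains, ref_labels = reference_set()
tree = build_reference_tree(query_domains, ref_domains)
annotations = annotate_family(records, domains, tree, ref_labels)

print(f"{'protein':<16}{'pattern':<36}{'group':<7}planted")
for ann in annotations:
    patterns = ";".join(ann.pattern_strings) or "-"
    planted = truth.proteins[ann.protein_id].group
    print(f"{ann.protein_id:<16}{patterns:<36}{ann.group.value:<7}{planted}")
print(
    f"\n{len(annotations)} of {len(records)} proteins carry a WRKY core; "
    "decoys are dropped. Pattern C-Xm-C-Xn-H-X-[H|C] is the zinc finger: "
    "m=4/5 with terminal H marks groups I/II, m=7 with terminal C group III/IV."
)
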