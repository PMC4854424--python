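"""Shared fixtures: a seeded synthetic family and its scan/classification."""

import pytest

from wrkycensus.classify import annotate_family, build_reference_tree
from wrkycensus.domain_scan import complete_domains, scan_proteome
from wrkycensus.synthetic_data import (
    GROUPS,
    FamilySpec,
    gen_proteins,
    reference_set,
)


@pytest.fixture(scope="session")
def family():
    """Two members per group plus four decoys, fixed seed."""
    spec = FamilySpec(n_per_group={g: 2 for g in GROUPS}, n_decoys=4, seed=7)
    records, truth = gen_proteins(spec)
    return records, truth


@pytest.fixture(scope="session")
def family_domains(family):
    records, _ = family
    return scan_proteome(records)


@pytest.fixture(scope="session")
def reference_tree(family, family_domains):
    records, _ = family
    query_domains = {}
    for rec in records:
        comp = complete_domains(family_domains[rec.id])
        if comp:
            s, e = comp[-1].span
            query_domains[rec.id] = rec.sequence[s:e]
    ref_domains, ref_labels = reference_set()
    tree = build_reference_tree(query_domains, ref_domains)
    return tree, ref_labels


@pytest.fixture(scope="session")
def family_annotations(family, family_domains, reference_tree):
    records, _ = family
    tree, labels = reference_tree
    return annotate_family(records, family_domains, tree=tree, reference_labels=labels)
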