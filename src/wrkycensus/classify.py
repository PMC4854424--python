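"""Group assignment and named-motif scanning for WRKY proteins.

The family splits into groups by domain count and zinc-finger geometry:

* group I — two complete C2H2 domains;
* group II — one C2H2 domain; subgroup IIc is recognised directly by
  its short first spacer (C-X4-C), while IIa/IIb/IId/IIe all share
  C-X5-C-X23-H-X-H and can only be separated by phylogenetic placement
  against labelled reference domains;
* group III — one C2HC domain (C-X7-C-X23-H-X-[H|C]);
* group IV — C2HC proteins that fall outside the group-III clade and
  are much longer than typical family members;
* NG — no group: incomplete domains or unresolvable placement.

The module also scans the short motifs the census reports alongside the
groups: the HARF motif diagnostic of subgroup IId (RTGHARFRR[A/G]P), the
LxxLL co-activator and LxLxLx repressor motifs, and heptad-spaced
leucine zippers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .domain_scan import ProteinRecord, WRKYDomain, complete_domains
from .physchem import PhyschemProfile, profile as physchem_profile
from .phylogeny import TreeNode, align_progressive, nj_tree, p_distance

logger = logging.getLogger(__name__)

GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III", "IV", "NG")
SUBGROUPS_NEEDING_TREE = ("IIa", "IIb", "IId", "IIe")

#: Proteins this much longer than typical members are group-IV candidates.
DEFAULT_DIVERGENCE_LENGTH = 800

HARF_RE = re.compile(r"(?=(RTGHARFRR[AG]P))")
LXXLL_RE = re.compile(r"(?=(L..LL))")
LXLXLX_RE = re.compile(r"(?=(L.L.L.))")
LXLXL_RE = re.compile(r"(?=(L.L.L))")


@dataclass(frozen=True)
class GroupLabel:
    value: str
    basis: str = "rule"  # rule | tree | rule+tree

    def __post_init__(self):
        if self.value not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.value!r}")


@dataclass
class MotifFlags:
    harf: bool
    leucine_zipper: bool
    lxxll: bool
    lxlxlx: bool
    positions: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class FamilyAnnotation:
    """One census row: domains, group, motifs, physicochemical profile."""

    protein_id: str
    domains: list[WRKYDomain]
    group: GroupLabel
    motifs: MotifFlags
    physchem: PhyschemProfile
    pattern_strings: list[str]


def assign_group_rule(domains: list[WRKYDomain]) -> str:
    """Spacing/finger-class rule; returns a group label, ``III-candidate``
    or ``II-unresolved`` (the latter two need tree placement)."""
    comp = complete_domains(domains)
    if len(comp) == 0:
        return "NG"
    if len(comp) >= 2:
        classes = {d.finger.finger_class for d in comp}
        if classes == {"C2H2"}:
            return "I"
        # mixed finger classes: label by the C-terminal domain
        logger.warning("mixed zinc-finger classes in one protein; using C-terminal domain")
        comp = [comp[-1]]
    d = comp[0]
    if d.finger.finger_class == "C2HC" or d.finger.m == 7:
        return "III-candidate"
    if d.finger.m == 4:
        return "IIc"
    return "II-unresolved"


def scan_named_motifs(
    sequence: str,
    zipper_leucines: int = 4,
    lxlxlx_trailing: bool = True,
) -> MotifFlags:
    """Scan HARF, LxxLL, LxLxLx and leucine-zipper motifs.

    The leucine zipper is called when ``zipper_leucines`` leucines occur
    at exact heptad spacing (position i, i+7, i+14, ...).
    """
    positions: dict[str, list[int]] = {}
    positions["harf"] = [m.start() for m in HARF_RE.finditer(sequence)]
    positions["lxxll"] = [m.start() for m in LXXLL_RE.finditer(sequence)]
    rep_re = LXLXLX_RE if lxlxlx_trailing else LXLXL_RE
    positions["lxlxlx"] = [m.start() for m in rep_re.finditer(sequence)]
    zips = []
    span = 7 * (zipper_leucines - 1)
    for i in range(len(sequence) - span):
        if all(sequence[i + 7 * k] == "L" for k in range(zipper_leucines)):
            zips.append(i)
    positions["leucine_zipper"] = zips
    return MotifFlags(
        harf=bool(positions["harf"]),
        leucine_zipper=bool(zips),
        lxxll=bool(positions["lxxll"]),
        lxlxlx=bool(positions["lxlxlx"]),
        positions=positions,
    )


def _smallest_side_with(tree: TreeNode, query: str, predicate) -> str | None:
    """Label of the smallest bipartition side containing the query whose
    reference labels satisfy the predicate; None when none qualifies."""
    all_names = set(tree.leaf_names())
    sides = []
    for node in tree.iter_internal():
        side = set(node.leaf_names())
        sides.append(side)
        sides.append(all_names - side)
    # leaf edges also define (trivial) sides; the query's own singleton
    # never contains references, so they can be skipped.
    sides = [s for s in sides if query in s]
    for side in sorted(sides, key=lambda s: (len(s), tuple(sorted(s)))):
        label = predicate(side)
        if label:
            return label
    return None


def resolve_subgroup(
    query_id: str,
    tree: TreeNode,
    reference_labels: dict[str, str],
    rule_result: str,
    protein_length: int,
    divergence_length: int = DEFAULT_DIVERGENCE_LENGTH,
) -> GroupLabel:
    """Resolve II-unresolved / III-candidate proteins by tree placement.

    II-unresolved: label of the smallest clade containing the query whose
    reference leaves are unanimous; nearest reference by path distance
    when no unanimous clade exists.  C2HC candidates: group III when the
    query sits inside the clade spanned by the group-III references;
    otherwise group IV when the protein exceeds the divergence length,
    else NG.
    """
    missing = [
        g for g in (*SUBGROUPS_NEEDING_TREE, "III")
        if g not in set(reference_labels.values())
    ]
    if missing:
        raise ValueError(f"missing subgroup exemplars: {missing}")

    def unanimous(side: set) -> str | None:
        labels = {reference_labels[x] for x in side if x in reference_labels}
        if len(labels) == 1:
            return labels.pop()
        return None

    label = _smallest_side_with(tree, query_id, unanimous)
    if label is None:
        label = _nearest_reference_label(tree, query_id, reference_labels)

    if rule_result == "III-candidate":
        # ordinary group-III members place with the III references; a
        # long protein that falls outside the clade the III references
        # span (e.g. sister to the whole group) is the divergent group IV
        inside = _inside_group_clade(tree, query_id, reference_labels, "III")
        if label == "III" and (protein_length <= divergence_length or inside):
            return GroupLabel("III", "rule+tree")
        if protein_length > divergence_length:
            return GroupLabel("IV", "rule+tree")
        return GroupLabel("NG", "rule+tree")

    if label in SUBGROUPS_NEEDING_TREE:
        return GroupLabel(label, "rule+tree")
    return GroupLabel("NG", "rule+tree")


def _inside_group_clade(
    tree: TreeNode, query: str, reference_labels: dict[str, str], group: str
) -> bool:
    """Is the query inside the smallest clade spanning all ``group``
    references?  Queries attached sister to (or beyond) that clade are
    outside it."""
    refs = {x for x, g in reference_labels.items() if g == group}
    all_names = set(tree.leaf_names())
    candidates = []
    for node in tree.iter_internal():
        side = set(node.leaf_names())
        for s in (side, all_names - side):
            if refs <= s:
                candidates.append(s)
    if not candidates:
        return False
    smallest = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
    return query in smallest


def _nearest_reference_label(
    tree: TreeNode, query: str, reference_labels: dict[str, str]
) -> str | None:
    dists = tree.path_distances()
    best = None
    for ref, label in sorted(reference_labels.items()):
        key = (query, ref) if query < ref else (ref, query)
        d = dists.get(key)
        if d is not None and (best is None or d < best[0] - 1e-12):
            best = (d, label)
    return best[1] if best else None


def build_reference_tree(
    query_domains: dict[str, str], reference_domains: dict[str, str]
) -> TreeNode:
    """NJ tree of query + reference domain sequences (p-distance)."""
    ids = list(query_domains) + list(reference_domains)
    seqs = list(query_domains.values()) + list(reference_domains.values())
    aln = align_progressive(ids, seqs)
    return nj_tree(p_distance(aln))


def annotate_family(
    proteins: list[ProteinRecord],
    domains: dict[str, list[WRKYDomain]],
    tree: TreeNode | None = None,
    reference_labels: dict[str, str] | None = None,
    divergence_length: int = DEFAULT_DIVERGENCE_LENGTH,
) -> list[FamilyAnnotation]:
    """Annotate every WRKY-positive protein (>= 1 core hit).

    Without a tree, II-unresolved proteins fall back to NG and C2HC
    candidates are split III/IV by the divergence length alone.
    """
    by_id = {p.id: p for p in proteins}
    unknown = set(domains) - set(by_id)
    if unknown:
        raise ValueError(f"domain table references unknown proteins: {sorted(unknown)}")
    annotations = []
    for pid, doms in domains.items():
        if not doms:
            continue
        protein = by_id[pid]
        rule = assign_group_rule(doms)
        if rule in ("II-unresolved", "III-candidate"):
            if tree is not None and reference_labels is not None:
                group = resolve_subgroup(
                    pid, tree, reference_labels, rule,
                    len(protein), divergence_length,
                )
            elif rule == "III-candidate":
                value = "IV" if len(protein) > divergence_length else "III"
                group = GroupLabel(value, "rule")
            else:
                group = GroupLabel("NG", "rule")
        else:
            group = GroupLabel(rule, "rule")
        annotations.append(
            FamilyAnnotation(
                protein_id=pid,
                domains=doms,
                group=group,
                motifs=scan_named_motifs(protein.sequence),
                physchem=physchem_profile(protein.sequence),
                pattern_strings=[
                    d.pattern_string for d in complete_domains(doms)
                ],
            )
        )
    return annotations
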