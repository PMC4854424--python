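"""Detection of WRKY domains in protein sequences.

A WRKY domain is an ~60-residue DNA-binding domain consisting of a
conserved heptapeptide core (canonically ``WRKYGQK``, with natural
variants such as ``WRKYGKK`` and ``WEKYGQK``) followed, some residues
downstream, by a zinc finger of the form ``C-Xm-C-Xn-H-X-[H|C]``.  The
spacer lengths *m* and *n* and the terminal residue (His for C2H2,
Cys for C2HC fingers) discriminate the family groups: group I proteins
carry two domains, group II one C2H2 domain, group III/IV one C2HC
domain.

This module finds core-motif hits, parses the downstream zinc finger
into its spacer geometry, and assembles per-protein domain inventories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Heptapeptide variants searched by default.
DEFAULT_VARIANTS = ("WRKYGQK", "WRKYGKK", "WEKYGQK")

#: Four-letter replacements of the motif start reported in highly
#: divergent family members.  Matched as the 4-mer followed by any three
#: residues; disabled unless explicitly requested because the full
#: seven-residue extension is not standardised.
FOUR_LETTER_REPLACEMENTS = (
    "WKKY", "WKRY", "WSKY", "WIKY", "WRIC", "WRMC", "WRRY", "WVKY",
)

#: Canonical core.
CANONICAL_CORE = "WRKYGQK"

#: Zinc-finger spacer lengths admitted by default: C-X{4,5,7}-C-X{22,23}-H-X-[H|C].
DEFAULT_M_VALUES = (4, 5, 7)
DEFAULT_N_VALUES = (22, 23)

#: Residues searched downstream of a core for the finger.
DEFAULT_FINGER_WINDOW = 120

_VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProteinRecord:
    """A protein sequence with optional gene linkage.

    Sequences are upper-cased at construction; characters outside the
    20-letter alphabet are replaced by ``X`` with a logged warning.
    """

    id: str
    sequence: str
    gene_id: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        if not set(seq) <= _VALID_ALPHABET:
            bad = sorted(set(seq) - _VALID_ALPHABET)
            logger.warning(
                "protein %s: replacing invalid residues %s with X", self.id, bad
            )
            seq = "".join(c if c in _VALID_ALPHABET else "X" for c in seq)
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoreHit:
    """A match of one heptapeptide core variant."""

    start: int
    peptide: str
    canonical: bool

    @property
    def end(self) -> int:
        """0-based exclusive end of the matched core."""
        return self.start + len(self.peptide)


@dataclass(frozen=True)
class ZincFinger:
    """Parsed zinc-finger geometry C-Xm-C-Xn-H-X-[H|C].

    Positions are 0-based offsets into the protein.  ``m`` counts the
    residues strictly between the two cysteines, ``n`` those between
    the second cysteine and the first histidine.
    """

    c1: int
    c2: int
    h1: int
    t: int

    def __post_init__(self) -> None:
        if not (self.c1 < self.c2 < self.h1 < self.t):
            raise ValueError("zinc-finger positions out of order")
        if self.t - self.h1 - 1 != 1:
            raise ValueError("terminal residue must follow H-X-[H|C] spacing")

    @property
    def m(self) -> int:
        return self.c2 - self.c1 - 1

    @property
    def n(self) -> int:
        return self.h1 - self.c2 - 1

    # terminal residue is set by the parser; stored separately so the
    # dataclass stays position-only and hashable
    terminal_residue: str = "H"

    @property
    def finger_class(self) -> str:
        """``C2H2`` when the terminal residue is His, ``C2HC`` for Cys."""
        return "C2H2" if self.terminal_residue == "H" else "C2HC"

    @property
    def pattern_string(self) -> str:
        tail = "H" if self.terminal_residue == "H" else "C"
        return f"C-X{self.m}-C-X{self.n}-H-X-{tail}"


@dataclass
class WRKYDomain:
    """A core hit plus (when found) its zinc finger."""

    core: CoreHit
    finger: ZincFinger | None = None

    @property
    def complete(self) -> bool:
        return self.finger is not None

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open span from core start to finger terminal."""
        if self.finger is not None:
            return (self.core.start, self.finger.t + 1)
        return (self.core.start, self.core.end)

    @property
    def pattern_string(self) -> str | None:
        return self.finger.pattern_string if self.finger else None


def find_cores(
    protein: ProteinRecord,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    include_four_letter: bool = False,
) -> list[CoreHit]:
    """Find every substring match of the configured core variants.

    Matches are reported left-to-right; overlapping matches are all
    reported.  ``X`` in the sequence never matches a motif position.
    """
    if not variants:
        raise ValueError("empty core-variant list")
    seq = protein.sequence
    hits: list[CoreHit] = []
    for start in range(len(seq)):
        for var in variants:
            if seq.startswith(var, start):
                hits.append(CoreHit(start, var, var == CANONICAL_CORE))
                break
        else:
            if include_four_letter:
                for var in FOUR_LETTER_REPLACEMENTS:
                    if seq.startswith(var, start) and start + 7 <= len(seq):
                        peptide = seq[start : start + 7]
                        if "X" not in peptide:
                            hits.append(CoreHit(start, peptide, False))
                        break
    return hits


def parse_finger(
    protein: ProteinRecord,
    core: CoreHit,
    window: int = DEFAULT_FINGER_WINDOW,
    m_values: Iterable[int] = DEFAULT_M_VALUES,
    n_values: Iterable[int] = DEFAULT_N_VALUES,
) -> ZincFinger | None:
    """Parse the first legal zinc finger downstream of a core hit.

    Searches at most ``window`` residues after the core for the
    arrangement ``C-Xm-C-Xn-H-X-[H|C]`` with *m*, *n* in the allowed
    sets; among arrangements the one with the smallest first-cysteine
    position wins, ties broken by smaller *m* then *n*.  Returns ``None``
    when no legal arrangement exists (incomplete domain).
    """
    if window < 40:
        raise ValueError("finger search window must be >= 40 residues")
    seq = protein.sequence
    if core.end > len(seq):
        raise ValueError("core does not belong to this protein")
    limit = min(len(seq), core.end + window)
    m_values = sorted(m_values)
    n_values = sorted(n_values)
    for c1 in range(core.end, limit):
        if seq[c1] != "C":
            continue
        for m in m_values:
            c2 = c1 + m + 1
            if c2 >= limit or seq[c2] != "C":
                continue
            for n in n_values:
                h1 = c2 + n + 1
                t = h1 + 2
                if t >= limit:
                    continue
                if seq[h1] == "H" and seq[t] in "HC":
                    return ZincFinger(c1, c2, h1, t, terminal_residue=seq[t])
    return None


def scan_protein(
    protein: ProteinRecord,
    variants: Sequence[str] = DEFAULT_VARIANTS,
    window: int = DEFAULT_FINGER_WINDOW,
    m_values: Iterable[int] = DEFAULT_M_VALUES,
    n_values: Iterable[int] = DEFAULT_N_VALUES,
    include_four_letter: bool = False,
) -> list[WRKYDomain]:
    """Scan one protein: cores, then finger parsing per core.

    Overlapping cores are all reported; when several cores share one
    finger region the caller keeps the first complete domain.  Domains
    are sorted by core start.
    """
    domains = [
        WRKYDomain(core, parse_finger(protein, core, window, m_values, n_values))
        for core in find_cores(protein, variants, include_four_letter)
    ]
    domains.sort(key=lambda d: d.core.start)
    return domains


def scan_proteome(
    proteins: Iterable[ProteinRecord],
    variants: Sequence[str] = DEFAULT_VARIANTS,
    window: int = DEFAULT_FINGER_WINDOW,
    m_values: Iterable[int] = DEFAULT_M_VALUES,
    n_values: Iterable[int] = DEFAULT_N_VALUES,
    include_four_letter: bool = False,
) -> dict[str, list[WRKYDomain]]:
    """Scan every protein; proteins without domains keep empty lists.

    Raises on duplicate protein identifiers.
    """
    result: dict[str, list[WRKYDomain]] = {}
    for protein in proteins:
        if protein.id in result:
            raise ValueError(f"duplicate protein id: {protein.id}")
        result[protein.id] = scan_protein(
            protein, variants, window, m_values, n_values, include_four_letter
        )
    return result


def complete_domains(domains: Iterable[WRKYDomain]) -> list[WRKYDomain]:
    """Domains with a parsed zinc finger, de-duplicated by finger.

    Overlapping cores can resolve to the same finger; the first core
    with a complete finger is kept per distinct finger position.
    """
    seen: set[int] = set()
    out = []
    for d in domains:
        if d.finger is None:
            continue
        if d.finger.c1 in seen:
            continue
        seen.add(d.finger.c1)
        out.append(d)
    return out
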