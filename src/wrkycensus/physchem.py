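"""Physicochemical profiling of proteins.

Computes the classical census-table descriptors: length, molecular
weight (average masses), isoelectric point (Henderson–Hasselbalch
bisection over the Bjellqvist or EMBOSS pKa set), grand average of
hydropathicity (GRAVY, Kyte–Doolittle scale), aliphatic index and the
Guruprasad instability index.  The constant tables ship with the
package as ``data/physchem_constants.json``.

Ambiguous residues ``X`` contribute the mean residue mass to the
molecular weight and are excluded from the denominators of the
composition statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

logger = logging.getLogger(__name__)

with resources.files("wrkycensus.data").joinpath("physchem_constants.json").open() as _fh:
    _C = json.load(_fh)

WATER = _C["water_mass"]
#: Average residue masses (free amino acid minus one water).
RESIDUE_MASS = {aa: w - WATER for aa, w in _C["amino_acid_weights"].items()}
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)
KYTE_DOOLITTLE = _C["kyte_doolittle"]
DIWV = _C["diwv"]
PKA_SETS = _C["pka_sets"]


@dataclass(frozen=True)
class PhyschemProfile:
    """Census-row physicochemical descriptors for one protein."""

    length: int
    mw: float       # daltons
    pi: float       # pH units, 2 decimals
    ai: float       # aliphatic index
    gravy: float    # mean Kyte-Doolittle hydropathy
    instability: float


def molecular_weight(sequence: str) -> float:
    """Average-mass molecular weight in daltons (residues + one water)."""
    total = WATER
    for aa in sequence:
        if aa == "X":
            logger.warning("X residue: using mean residue mass")
            total += _MEAN_RESIDUE_MASS
        else:
            total += RESIDUE_MASS[aa]
    return total


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity over scorable residues."""
    vals = [KYTE_DOOLITTLE[aa] for aa in sequence if aa != "X"]
    if not vals:
        raise ValueError("no scorable residues")
    return sum(vals) / len(vals)


def aliphatic_index(sequence: str) -> float:
    """X(Ala) + 2.9 X(Val) + 3.9 (X(Ile)+X(Leu)), X = mole percent."""
    scorable = [aa for aa in sequence if aa != "X"]
    if not scorable:
        return 0.0
    n = len(scorable)
    pct = lambda a: 100.0 * scorable.count(a) / n
    return pct("A") + 2.9 * pct("V") + 3.9 * (pct("I") + pct("L"))


def _net_charge(ph: float, counts: dict[str, int], pka: dict) -> float:
    pos = sum(
        cnt / (1.0 + 10.0 ** (ph - pka["positive"][g]))
        for g, cnt in counts.items()
        if g in pka["positive"]
    )
    neg = sum(
        cnt / (1.0 + 10.0 ** (pka["negative"][g] - ph))
        for g, cnt in counts.items()
        if g in pka["negative"]
    )
    return pos - neg


def isoelectric_point(sequence: str, pka_set: str = "bjellqvist") -> float:
    """pH of zero net charge, by bisection to 1e-4, reported to 2 decimals.

    Charge is the Henderson–Hasselbalch sum over the two termini and the
    D, E, C, Y, H, K, R side chains.
    """
    pka = dict(PKA_SETS[pka_set])
    # Bjellqvist assigns terminus pKa values specific to the terminal residue
    nterm = pka.get("nterm_by_residue", {}).get(sequence[0], pka["positive"]["Nterm"])
    cterm = pka.get("cterm_by_residue", {}).get(sequence[-1], pka["negative"]["Cterm"])
    pka = {
        "positive": {**pka["positive"], "Nterm": nterm},
        "negative": {**pka["negative"], "Cterm": cterm},
    }
    counts: dict[str, int] = {"Nterm": 1, "Cterm": 1}
    for aa in "DECYHKR":
        c = sequence.count(aa)
        if c:
            counts[aa] = c
    lo, hi = 0.0, 14.0
    # termini guarantee charge(0) > 0 > charge(14)
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if _net_charge(mid, counts, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)


def instability_index(sequence: str) -> float:
    """Guruprasad dipeptide-weight instability index, (10/L) * sum DIWV."""
    scorable = [aa for aa in sequence if aa != "X"]
    if len(scorable) < 2:
        raise ValueError("instability index requires >= 2 scorable residues")
    total = sum(
        DIWV[a][b] for a, b in zip(scorable, scorable[1:])
    )
    return (10.0 / len(scorable)) * total


def profile(sequence: str, pka_set: str = "bjellqvist") -> PhyschemProfile:
    """Full physicochemical profile of one sequence."""
    return PhyschemProfile(
        length=len(sequence),
        mw=molecular_weight(sequence),
        pi=isoelectric_point(sequence, pka_set),
        ai=aliphatic_index(sequence),
        gravy=gravy(sequence),
        instability=instability_index(sequence),
    )
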