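"""Domain alignment, distances, neighbor-joining and bootstrap.

The family classification rests on a phylogeny of the ~60-residue WRKY
domains.  This module provides the full distance pipeline:

* progressive multiple alignment — pairwise Gotoh (affine-gap) global
  alignments give a distance estimate, an average-linkage (UPGMA) guide
  tree orders profile–profile merges scored by sum-of-pairs BLOSUM62;
* p-distance (share of mismatched residues over columns without gaps),
  with a Poisson correction available;
* Saitou–Nei neighbor joining with a fixed lowest-index tie-break, so
  results are deterministic; negative branch lengths are clamped to
  zero with a warning;
* nonparametric bootstrap: columns resampled with replacement, support
  of each internal bipartition of the full-data tree as the percentage
  of replicate trees containing it.

On additive distance matrices NJ recovers the generating topology and
branch lengths exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def _blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            out[i, j] = mat[a][b]
    return out


_B62 = _blosum62()


@dataclass
class DomainAlignment:
    """A multiple alignment: equal-length rows over residues and ``-``."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace("-", "")

    def subsample_columns(self, columns: np.ndarray) -> "DomainAlignment":
        rows = ["".join(r[c] for c in columns) for r in self.rows]
        return DomainAlignment(list(self.ids), rows)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        self.matrix = m


class TreeNode:
    """Node of an (un)rooted phylogenetic tree.

    NJ output is an unrooted tree represented with a trifurcating root.
    ``support`` on internal nodes is bootstrap support in [0, 100].
    """

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = length
        self.support = None
        self.children: list[TreeNode] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def iter_internal(self):
        """Internal nodes below the root (each defines one bipartition)."""
        for child in self.children:
            yield from child._iter_internal_below()

    def _iter_internal_below(self):
        if not self.is_leaf:
            yield self
            for c in self.children:
                yield from c._iter_internal_below()

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal bipartitions of the unrooted tree.

        Each is the leaf set on the side *not* containing the reference
        leaf (the lexicographically smallest leaf name); trivial splits
        (single leaves, full set) are excluded.
        """
        all_names = set(self.leaf_names())
        ref = min(all_names)
        out = set()
        for node in self.iter_internal():
            side = frozenset(node.leaf_names())
            if ref in side:
                side = frozenset(all_names - side)
            if 1 < len(side) < len(all_names) - 1:
                out.add(side)
        return out

    def _bipartition_of(self, node: "TreeNode") -> frozenset | None:
        all_names = set(self.leaf_names())
        ref = min(all_names)
        side = frozenset(node.leaf_names())
        if ref in side:
            side = frozenset(all_names - side)
        if 1 < len(side) < len(all_names) - 1:
            return side
        return None

    def path_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (sum of branch lengths)."""
        dist: dict[tuple[str, str], float] = {}

        def walk(node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for c in node.children:
                d = walk(c)
                below.append({k: v + c.length for k, v in d.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            key = (a, b) if a < b else (b, a)
                            dist[key] = da + db
            merged = {}
            for d in below:
                merged.update(d)
            return merged

        walk(self)
        return dist

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node, with_length=True):
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                s = f"({inner}){label}"
            if with_length:
                s += f":{round(node.length, decimals):g}"
            return s

        inner = ",".join(fmt(c) for c in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label};"


def align_pair(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> tuple[str, str]:
    """Global affine-gap (Gotoh) alignment of two sequences."""
    aln = _merge_profiles([a], [b], gap_open, gap_extend)
    return aln[0], aln[1]


def _profile_counts(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, 20))
    for row in rows:
        for i, aa in enumerate(row):
            k = _AA_INDEX.get(aa)
            if k is not None:
                counts[i, k] += 1
    return counts


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> list[str]:
    """Profile–profile Gotoh alignment; returns rows_a' + rows_b'."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    na, nb = len(rows_a), len(rows_b)
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    S = ca @ _B62 @ cb.T / (na * nb)

    NEG = -math.inf
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Iy[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        Si = S[i - 1]
        for j in range(1, lb + 1):
            M[i, j] = Si[j - 1] + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)

    # traceback, deterministic preference M > Ix > Iy
    i, j = la, lb
    state = max(
        [("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])], key=lambda t: t[1]
    )[0]
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            cols.append((i - 1, j - 1))
            prev = S[i - 1][j - 1]
            cands = [("M", M[i - 1, j - 1]), ("Ix", Ix[i - 1, j - 1]), ("Iy", Iy[i - 1, j - 1])]
            target = M[i, j] - prev
            state = next(s for s, v in cands if math.isclose(v, target, abs_tol=1e-9))
            i, j = i - 1, j - 1
        elif state == "Ix":
            cols.append((i - 1, None))
            if i == 1 and j == 0:
                state = "M"
            elif math.isclose(Ix[i, j], M[i - 1, j] - gap_open, abs_tol=1e-9):
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:
            cols.append((None, j - 1))
            if j == 1 and i == 0:
                state = "M"
            elif math.isclose(Iy[i, j], M[i, j - 1] - gap_open, abs_tol=1e-9):
                state = "M"
            else:
                state = "Iy"
            j -= 1
    cols.reverse()

    out_a = ["".join(r[ia] if ia is not None else "-" for ia, _ in cols) for r in rows_a]
    out_b = ["".join(r[jb] if jb is not None else "-" for _, jb in cols) for r in rows_b]
    return out_a + out_b


def align_progressive(
    ids: list[str],
    sequences: list[str],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> DomainAlignment:
    """Progressive multiple alignment over a UPGMA guide tree."""
    if len(sequences) < 2:
        raise ValueError("alignment requires >= 2 sequences")
    for sid, s in zip(ids, sequences):
        if not s:
            raise ValueError(f"empty sequence: {sid}")
    if len(sequences) == 2:
        a, b = align_pair(sequences[0], sequences[1], gap_open, gap_extend)
        return DomainAlignment(list(ids), [a, b])

    n = len(sequences)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = align_pair(sequences[i], sequences[j], gap_open, gap_extend)
            cond.append(_pairwise_p(ra, rb))
    Z = linkage(np.array(cond), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [sequences[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ia, ib = clusters.pop(int(a)), clusters.pop(int(b))
        merged_rows = _merge_profiles(ia[1], ib[1], gap_open, gap_extend)
        clusters[n + k] = (ia[0] + ib[0], merged_rows)
    order, rows = clusters.popitem()[1]
    # restore input order of rows
    by_input = dict(zip(order, rows))
    return DomainAlignment(list(ids), [by_input[i] for i in range(n)])


def _pairwise_p(row_a: str, row_b: str) -> float:
    used = mism = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        used += 1
        if x != y:
            mism += 1
    return mism / used if used else 1.0


def p_distance(alignment: DomainAlignment, poisson: bool = False) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where neither row gaps.

    With ``poisson=True`` applies the Poisson correction -ln(1 - p).
    """
    n = len(alignment.ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            used = mism = 0
            for x, y in zip(alignment.rows[i], alignment.rows[j]):
                if x == "-" or y == "-":
                    continue
                used += 1
                if x != y:
                    mism += 1
            if used == 0:
                raise ValueError(
                    f"no comparable columns for pair "
                    f"({alignment.ids[i]}, {alignment.ids[j]})"
                )
            p = mism / used
            if poisson:
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined for p >= 1")
                p = -math.log(1.0 - p)
            m[i, j] = m[j, i] = p
    return DistanceMatrix(list(alignment.ids), m)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Agglomeration ties are broken by the lowest (row, column) index pair
    in the current matrix, making the result deterministic.  Negative
    branch lengths are clamped to zero with a warning.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    nodes = [TreeNode(name=i) for i in dm.ids]
    D = dm.matrix.copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        N = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(N):
            for j in range(i + 1, N):
                q = (N - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (N - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(N) if k not in (i, j)]
        D2 = np.zeros((N - 1, N - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = clamp(la), clamp(lb), clamp(lc)
    return TreeNode(children=[a, b, c])


def bootstrap(
    alignment: DomainAlignment,
    replicates: int = 1000,
    seed: int = 0,
    poisson: bool = False,
) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; support of an
    internal bipartition is the percentage of replicate NJ trees that
    contain it.  Replicates whose resample leaves some pair with no
    comparable columns are counted as not supporting any bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    full = nj_tree(p_distance(alignment, poisson))
    counts: dict[frozenset, int] = {bp: 0 for bp in full.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        try:
            rep = nj_tree(p_distance(alignment.subsample_columns(cols), poisson))
        except ValueError:
            continue
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for node in full.iter_internal():
        bp = full._bipartition_of(node)
        if bp is not None:
            node.support = round(100.0 * counts[bp] / replicates, 1)
    return full
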