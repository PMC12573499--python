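"""Amplicon classification by TN93 distances, neighbor-joining, bootstrap.

The use-case is typing short (~260 bp) 18S V4 amplicons against a labeled
reference panel: compute Tamura-Nei (1993) pairwise distances, build a
neighbor-joining tree with bootstrap supports for reporting, and assign each
query to the taxon class of its nearest reference. The TN93 model separates
the two transition types (A<->G within purines, C<->T within pyrimidines)
from transversions and allows unequal base frequencies, which matters for
rRNA where transition saturation is uneven.

Distances use pairwise deletion by default: each pair is scored over the
sites where both sequences carry an unambiguous A/C/G/T. Complete deletion
(drop any column with a gap/ambiguity in any row) is available for matrix
construction. Negative NJ branch-length estimates are clamped to zero, the
standard convention, with a log note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import UnalignableQueryError, ZeroUsableSitesError
from .seq_io import Alignment, SequenceRecord, TaxonMap

log = logging.getLogger(__name__)

_ACGT = {"A": 0, "C": 1, "G": 2, "T": 3}
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class DistanceComponents:
    """Sufficient statistics of one pairwise TN93 computation."""

    p1: float          # proportion of purine transitions (A<->G)
    p2: float          # proportion of pyrimidine transitions (C<->T)
    q: float           # proportion of transversions
    pi: tuple[float, float, float, float]   # pooled A,C,G,T frequencies
    usable_sites: int

    def __post_init__(self) -> None:
        assert self.p1 >= 0 and self.p2 >= 0 and self.q >= 0
        assert self.p1 + self.p2 + self.q <= 1 + 1e-12


def _pair_stats(a: str, b: str) -> DistanceComponents:
    n = p1 = p2 = q = 0
    counts = [0, 0, 0, 0]
    for ca, cb in zip(a, b):
        ia = _ACGT.get(ca)
        ib = _ACGT.get(cb)
        if ia is None or ib is None:
            continue
        n += 1
        counts[ia] += 1
        counts[ib] += 1
        if ia != ib:
            pair = frozenset((ca, cb))
            if pair == frozenset("AG"):
                p1 += 1
            elif pair == frozenset("CT"):
                p2 += 1
            else:
                q += 1
    if n == 0:
        raise ZeroUsableSitesError("no shared unambiguous sites")
    total = 2 * n
    return DistanceComponents(
        p1=p1 / n, p2=p2 / n, q=q / n,
        pi=tuple(c / total for c in counts),
        usable_sites=n,
    )


def tn93_from_components(comp: DistanceComponents) -> float:
    """The TN93 distance estimator from observed proportions and pooled
    frequencies; returns inf when any logarithm argument is non-positive
    (substitution saturation)."""
    pa, pc, pg, pt = comp.pi
    pr, py = pa + pg, pc + pt
    if pr == 0 or py == 0:
        # degenerate composition: no purines or no pyrimidines observed
        return math.inf if comp.p1 + comp.p2 + comp.q > 0 else 0.0
    k1 = 2 * pa * pg / pr
    k2 = 2 * pt * pc / py
    k3 = 2 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    d = 0.0
    for k, w in (
        (k1, 1 - (comp.p1 / k1 if k1 > 0 else 0.0) - comp.q / (2 * pr)),
        (k2, 1 - (comp.p2 / k2 if k2 > 0 else 0.0) - comp.q / (2 * py)),
        (k3, 1 - comp.q / (2 * pr * py)),
    ):
        if k == 0:
            continue
        if w <= 0:
            return math.inf
        d -= k * math.log(w)
    return max(d, 0.0)


def tn93_distance(a: str | SequenceRecord, b: str | SequenceRecord) -> tuple[float, DistanceComponents]:
    """TN93 distance between two aligned sequences (pairwise deletion).

    Sites carrying a gap or ambiguity code in either sequence are excluded.
    Saturated pairs come back as ``inf``; callers decide how to react.
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must be aligned to equal length")
    comp = _pair_stats(sa, sb)
    return tn93_from_components(comp), comp


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray           # symmetric, zero diagonal; inf = saturated

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.ids), len(self.ids))

    @property
    def has_saturated_pairs(self) -> bool:
        return bool(np.isinf(self.values).any())

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)])


def _complete_deletion(alignment: Alignment) -> Alignment:
    rows = [r.sequence for r in alignment]
    keep = [
        i for i in range(alignment.length)
        if all(row[i] in _ACGT for row in rows)
    ]
    return Alignment(tuple(
        SequenceRecord(r.id, "".join(r.sequence[i] for i in keep), r.description)
        for r in alignment
    ))


def build_distance_matrix(
    alignment: Alignment, *, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All-pairs TN93 matrix (symmetric by construction).

    ``deletion='complete'`` drops every column containing a gap/ambiguity in
    any row before scoring; ``'pairwise'`` (default) filters per pair.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 rows")
    if deletion == "complete":
        alignment = _complete_deletion(alignment)
    n = len(alignment)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = tn93_distance(alignment.records[i], alignment.records[j])
            values[i, j] = values[j, i] = d
    if np.isinf(values).any():
        log.warning("distance matrix contains saturated (infinite) pairs")
    return DistanceMatrix(alignment.ids, values)


# --- trees ----------------------------------------------------------------


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def _min_leaf(self) -> str:
        return min(lf.name for lf in self.leaves())

    def canonicalize(self) -> None:
        """Sort children by smallest descendant leaf name, recursively, so
        isomorphic trees render to identical Newick."""
        for c in self.children:
            c.canonicalize()
        self.children.sort(key=lambda c: c._min_leaf())

    def to_newick(self, *, with_support: bool = False) -> str:
        return self._newick_inner(with_support) + ";"

    def _newick_inner(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_inner(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}:{self.length:.6f}"


@dataclass
class Tree:
    """Unrooted tree stored with a degree-3 (or star) top-level node."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each encoded as the side NOT
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_names
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                parts.add(side)
            return below

        walk(self.root)
        return parts

    def annotate_supports(self, support: dict[frozenset[str], float]) -> None:
        all_leaves = self.leaf_names
        anchor = min(all_leaves)

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                node.support = support.get(side, 0.0)
            return below

        walk(self.root)

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf distances along branches (for additivity checks)."""
        names = sorted(self.leaf_names)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for c in node.children:
                m = {k: v + c.length for k, v in walk(c).items()}
                child_maps.append(m)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for a, da in child_maps[i].items():
                        for b, db in child_maps[j].items():
                            dist[index[a], index[b]] = dist[index[b], index[a]] = da + db
                below = {k: v for m in child_maps for k, v in m.items()}
            return below

        walk(self.root)
        return DistanceMatrix(tuple(names), dist)

    def to_newick(self, *, with_support: bool = False) -> str:
        self.root.canonicalize()
        return self.root.to_newick(with_support=with_support)


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Canonical neighbor-joining (Q-criterion).

    Ties on the Q matrix break toward the lowest (row, column) index pair in
    the current working order, which makes the construction deterministic.
    Additive input matrices are reproduced exactly by the tree's path
    lengths. Negative branch-length estimates are clamped to zero.
    """
    n0 = len(matrix.ids)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.isinf(matrix.values).any():
        raise ValueError("cannot build a tree from saturated (infinite) distances")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    d = matrix.values.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamped negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin on the flattened array scans row-major
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        vi = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        vj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        parent = TreeNode()
        nodes[i].length, nodes[j].length = vi, vj
        parent.children = [nodes[i], nodes[j]]
        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return Tree(root)


def bootstrap_supports(
    alignment: Alignment,
    replicates: int = 100,
    seed: int = 0,
    *,
    deletion: str = "pairwise",
) -> Tree:
    """NJ tree on the full alignment with bootstrap supports in [0, 100].

    Columns are resampled with replacement per replicate; support for each
    internal bipartition of the full-data tree is the percentage of
    replicate trees containing it. Deterministic under a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if alignment.length < 2:
        raise ValueError("alignment too short to resample")
    full = nj_tree(build_distance_matrix(alignment, deletion=deletion))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in full.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = alignment.length
    rows = [r.sequence for r in alignment]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = Alignment(tuple(
            SequenceRecord(r.id, "".join(rows[k][c] for c in cols))
            for k, r in enumerate(alignment.records)
        ))
        try:
            rep_tree = nj_tree(build_distance_matrix(rep, deletion=deletion))
        except (ValueError, ZeroUsableSitesError):
            continue  # saturated replicate contributes no support
        rep_parts = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    full.annotate_supports(support)
    return full


# --- query assignment -----------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    query_id: str
    assigned_class: str
    nearest_ref: str
    distance: float
    margin: float
    ambiguous: bool
    offset: int                    # 0-based column offset of the placement


def _place_query(query: str, alignment: Alignment, min_identity: float) -> int:
    """Best ungapped placement offset of the query on the reference columns
    (highest identity to any single reference)."""
    if len(query) > alignment.length:
        raise UnalignableQueryError(
            f"query ({len(query)} nt) longer than reference alignment "
            f"({alignment.length} cols)"
        )
    best_offset, best_ident = -1, -1.0
    for offset in range(alignment.length - len(query) + 1):
        for ref in alignment:
            window = ref.sequence[offset:offset + len(query)]
            ident = sum(a == b for a, b in zip(query, window)) / len(query)
            if ident > best_ident:
                best_ident, best_offset = ident, offset
    if best_ident < min_identity:
        raise UnalignableQueryError(
            f"best placement identity {best_ident:.2f} below {min_identity:.2f}"
        )
    return best_offset


def assign_taxon(
    query: SequenceRecord,
    ref_alignment: Alignment,
    taxa: TaxonMap,
    *,
    min_identity: float = 0.5,
    group_key: str = "class",
    tie_tolerance: float = 1e-12,
) -> Assignment:
    """Assign a query to the taxon class of its nearest reference by TN93.

    The query is placed on the reference coordinates by the best ungapped
    offset (pre-aligned full-length queries place at offset 0 trivially).
    The margin is the distance gap to the nearest reference of any *other*
    class; a zero gap within tolerance raises the ambiguous flag.
    """
    offset = _place_query(query.sequence, ref_alignment, min_identity)
    window = slice(offset, offset + len(query.sequence))
    scored: list[tuple[float, str, str]] = []
    for ref in ref_alignment:
        if ref.id not in taxa:
            continue
        d, _ = tn93_distance(query.sequence, ref.sequence[window])
        scored.append((d, ref.id, taxa.group_of(ref.id, group_key)))
    if not scored:
        raise ValueError("no labeled references to assign against")
    scored.sort(key=lambda t: (t[0], t[1]))
    d0, ref0, cls0 = scored[0]
    other = [t for t in scored if t[2] != cls0]
    margin = (other[0][0] - d0) if other else math.inf
    ambiguous = bool(other) and margin <= tie_tolerance
    return Assignment(
        query_id=query.id,
        assigned_class=cls0,
        nearest_ref=ref0,
        distance=d0,
        margin=margin,
        ambiguous=ambiguous,
        offset=offset,
    )
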