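"""Distance-based subfamily classification and nomenclature.

Queries are classified by their distances to a panel of function-known
reference AQPs: pairwise global alignments give identity fractions, the
distance is 1 - identity (optionally Poisson-corrected), a Saitou-Nei
neighbor-joining tree summarizes the family, and each query inherits the
subfamily/class of its nearest reference.  Proposed names follow the
"<species prefix><class>;<index>" convention, reusing the nearest
reference's index when free and otherwise the smallest unused one.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from io import StringIO

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .features import AlignParams, global_align
from .seqio import ProteinSequence, ReferenceAnchor


@dataclass(frozen=True)
class SubfamilyCall:
    """A query's subfamily/class assignment with its distance support.

    ``support`` is the margin between the nearest reference of any other
    subfamily and the nearest reference overall; larger means a cleaner
    separation between clades.
    """

    query_id: str
    subfamily: str
    class_label: str
    proposed_name: str
    nearest_reference_id: str
    support: float


def pairwise_distance_matrix(seqs: list[ProteinSequence],
                             params: AlignParams = AlignParams(),
                             correction: str | None = None) -> DistanceMatrix:
    """All-vs-all distances d(i,j) = 1 - identity from global alignments.

    ``correction="poisson"`` applies -ln(identity), the standard Poisson
    multiple-hit correction (capped at 10 for disjoint sequences).
    """
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in distance matrix input")
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(seqs[i], seqs[j], params)
        if correction == "poisson":
            dist = -np.log(aln.identity) if aln.identity > 0 else 10.0
            dist = min(dist, 10.0)
        else:
            dist = 1.0 - aln.identity
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor joining (Saitou-Nei)

class _Node:
    __slots__ = ("name", "children")  # children: list of (node, branch length)

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return _quote_label(self.name)
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def _quote_label(name: str) -> str:
    if any(c in name for c in ";(),:[] '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted ``skbio.TreeNode``.

    At each step the pair minimizing the Q-criterion
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is joined, branch
    lengths follow the standard NJ formulas, and negative lengths are
    clamped to zero.  Ties resolve to the lexicographically first index
    pair, making the topology deterministic.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = np.array(dm.data, dtype=float)
    nodes = [_Node(name=i) for i in ids]
    active = list(range(len(ids)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)  # first minimum in C order
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new internal node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for c in active:
            if c in (i, j):
                continue
            d[k_new, c] = d[c, k_new] = 0.5 * (d[i, c] + d[j, c] - dij)
        nodes.append(new)
        active = [c for c in active if c not in (i, j)] + [k_new]

    # three remaining nodes: the unique unrooted topology, closed-form lengths
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = _Node(children=[(nodes[i], max(li, 0.0)),
                           (nodes[j], max(lj, 0.0)),
                           (nodes[k], max(lk, 0.0))])
    return TreeNode.read(StringIO(root.newick()))


# ---------------------------------------------------------------------------
# Assignment and nomenclature

def assign_subfamily(query_id: str, refs: list[ReferenceAnchor],
                     dm: DistanceMatrix,
                     species_prefix: str = "Es",
                     existing_names: set[str] | None = None) -> SubfamilyCall:
    """Subfamily/class of the nearest reference, with a distance margin.

    ``support`` = d(nearest reference of any other subfamily) - d(nearest
    reference).  Distance ties keep the reference table order.
    """
    ref_ids = {r.id for r in refs}
    present = [r for r in refs if r.id in set(dm.ids)]
    if not present:
        raise ValueError("no reference present in the distance matrix")
    if query_id not in set(dm.ids):
        raise ValueError(f"query {query_id!r} absent from the distance matrix")
    dists = [dm[query_id, r.id] for r in present]
    best_idx = int(np.argmin(dists))  # argmin keeps the first (table-order) tie
    best = present[best_idx]
    other = [dist for r, dist in zip(present, dists) if r.subfamily != best.subfamily]
    support = (min(other) - dists[best_idx]) if other else float("inf")
    call = SubfamilyCall(query_id=query_id, subfamily=best.subfamily,
                         class_label=best.class_label, proposed_name="",
                         nearest_reference_id=best.id, support=support)
    name = propose_name(call, existing_names or set(), species_prefix)
    return SubfamilyCall(query_id=query_id, subfamily=best.subfamily,
                         class_label=best.class_label, proposed_name=name,
                         nearest_reference_id=best.id, support=support)


def classify_queries(queries: list[ProteinSequence],
                     refs: list[ReferenceAnchor],
                     params: AlignParams = AlignParams(),
                     species_prefix: str = "Es",
                     dm: DistanceMatrix | None = None) -> list[SubfamilyCall]:
    """Classify and name every query against the panel (shared namespace).

    Names are assigned in input order so that two queries nearest the same
    reference receive distinct indices.
    """
    if dm is None:
        dm = pairwise_distance_matrix([q for q in queries] + [r.sequence for r in refs],
                                      params)
    taken: set[str] = set()
    calls = []
    for q in queries:
        call = assign_subfamily(q.id, refs, dm, species_prefix, taken)
        taken.add(call.proposed_name)
        calls.append(call)
    return calls


def propose_name(call: SubfamilyCall, existing_names: set[str],
                 species_prefix: str = "Es") -> str:
    """Name a query after its nearest reference's class and index.

    ``<prefix><class>;<index>`` where the index is the nearest reference's
    own index if that name is unused, otherwise the smallest unused
    positive integer within the class.
    """
    m = re.search(r";(\d+)$", call.nearest_reference_id)
    ref_index = int(m.group(1)) if m else 1
    candidate = f"{species_prefix}{call.class_label};{ref_index}"
    if candidate not in existing_names:
        return candidate
    index = 1
    while f"{species_prefix}{call.class_label};{index}" in existing_names:
        index += 1
    return f"{species_prefix}{call.class_label};{index}"


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree's leaf set.

    Each split is canonicalized as the side not containing the
    alphabetically first leaf, so topologies compare as plain set
    equality.
    """
    leaves = sorted(n.name for n in tree.tips())
    first = leaves[0]
    full = set(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 2 <= len(side) <= len(full) - 2:
            splits.add(frozenset(side if first not in side else full - side))
    return splits


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a PHYLIP square-format distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{v:.6f}" for v in dm.data[i])
            fh.write(f"{name:<12s}{row}\n")
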