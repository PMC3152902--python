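"""Segment trees and group-level topology congruence.

Pipeline: Kimura 2-parameter distances under complete deletion (every column
containing any gap or N in any strain is dropped), neighbor-joining with a
deterministic tie-break, nonparametric bootstrap over retained columns, and a
collapsed group-level topology comparison.  Two segment trees are congruent
when, after collapsing each maximal monophyletic same-group clade to a single
leaf, the rooted topologies are identical (Robinson-Foulds distance 0 with
matched leaf multisets); groups that fail monophyly are flagged paraphyletic
and contribute one leaf per maximal clade.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import dendropy
import numpy as np

from .alignment_io import GroupedAlignment
from .conversion_detect import encode_sequences

SATURATION_CAP = 5.0


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise K2P distances with saturation bookkeeping."""

    strains: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal
    n_sites_used: int
    saturated: frozenset[tuple[str, str]] = frozenset()

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.strains.index(a), self.strains.index(b)])


def complete_deletion(aln: GroupedAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Encoded residue matrix restricted to columns with no gap/N anywhere.

    Returns (matrix over all strains in sorted order, kept column indices).
    The retained column set depends only on column content, never on strain
    order.
    """
    strains = sorted(aln.sequences)
    mat = encode_sequences(aln, strains)
    keep = np.flatnonzero((mat >= 0).all(axis=0))
    return mat[:, keep], keep


def k2p_from_counts(p: float, q: float) -> float:
    """K2P distance from transition fraction P and transversion fraction Q.

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)); returns inf when the
    argument is non-positive (saturated pair).
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distances(
    aln: GroupedAlignment, cap_saturated: bool = False
) -> DistanceMatrix:
    """K2P distance matrix under complete deletion.

    Saturated pairs (log argument <= 0) raise by default; with
    ``cap_saturated`` they are set to SATURATION_CAP and flagged instead.
    """
    if len(aln.sequences) < 3:
        raise ValueError("need >= 3 strains for a distance matrix")
    mat, keep = complete_deletion(aln)
    if keep.size == 0:
        raise ValueError(
            f"segment {aln.segment_id}: no columns left after complete deletion"
        )
    strains = tuple(sorted(aln.sequences))
    n = len(strains)
    L = keep.size
    dm = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            diff = a != b
            ts = diff & (((a + b) == 2) | ((a + b) == 4))  # A<->G, C<->T
            p = float(ts.sum()) / L
            q = float(diff.sum() - ts.sum()) / L
            d = k2p_from_counts(p, q)
            if math.isinf(d):
                if not cap_saturated:
                    raise ValueError(
                        f"saturated K2P distance between {strains[i]!r} and "
                        f"{strains[j]!r}; pass cap_saturated=True to proceed"
                    )
                saturated.add((strains[i], strains[j]))
                d = SATURATION_CAP
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(
        strains=strains,
        matrix=dm,
        n_sites_used=int(L),
        saturated=frozenset(saturated),
    )


def nj_tree(
    dm: DistanceMatrix,
    outgroup: str | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei Q-criterion), rooted on the outgroup.

    Ties in the Q-criterion are broken lexicographically on the smallest
    strain id contained in each candidate cluster, so the topology does not
    depend on input order.  Without an outgroup the (arbitrarily rooted)
    unrooted tree is returned.
    """
    names = sorted(dm.strains)
    if len(names) < 3:
        raise ValueError("need >= 3 strains for neighbor joining")
    order = [dm.strains.index(s) for s in names]
    D = dm.matrix[np.ix_(order, order)].astype(float).copy()
    tns = taxon_namespace or dendropy.TaxonNamespace(names)
    nodes: list[dendropy.Node] = []
    for s in names:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(s) or tns.new_taxon(s)
        nodes.append(node)
    keys = list(names)  # canonical key: smallest leaf id in the cluster

    while len(nodes) > 2:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        bi = bj = -1
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                ka, kb = sorted((keys[i], keys[j]))
                cand = (q, ka, kb)
                if best is None or cand < best:
                    best, bi, bj = cand, i, j
        vi = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * (n - 2))
        vj = D[bi, bj] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[bi])
        nodes[bi].edge.length = vi
        parent.add_child(nodes[bj])
        nodes[bj].edge.length = vj
        new_row = 0.5 * (D[bi, :] + D[bj, :] - D[bi, bj])
        keep = [x for x in range(n) if x not in (bi, bj)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[bi], keys[bj])]

    root = dendropy.Node()
    half = D[0, 1] / 2.0
    for node in nodes:
        root.add_child(node)
        node.edge.length = half
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            import logging

            logging.getLogger(__name__).warning(
                "outgroup %r not in tree; returning unrooted tree", outgroup
            )
            return tree
        edge_len = og.edge.length or 0.0
        tree.reroot_at_edge(
            og.edge, length1=edge_len / 2.0, length2=edge_len / 2.0
        )
    return tree


def _internal_bitmasks(tree: dendropy.Tree) -> set[int]:
    tree.encode_bipartitions()
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.tail_node is None:
            continue
        out.add(int(edge.bipartition.split_bitmask))
    return out


def bootstrap_support(
    aln: GroupedAlignment,
    outgroup: str | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    cap_saturated: bool = False,
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap support on internal nodes.

    Columns of the complete-deletion alignment are resampled with
    replacement; support is the fraction of replicate NJ trees containing
    each internal bipartition of the point-estimate tree, stored as the
    internal node label (3-decimal string).
    """
    dm = k2p_distances(aln, cap_saturated=cap_saturated)
    tree = nj_tree(dm, outgroup=outgroup)
    tns = tree.taxon_namespace

    mat, keep = complete_deletion(aln)
    strains = tuple(sorted(aln.sequences))
    n, L = len(strains), keep.size
    # per-column transition / transversion indicators per pair
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ts_mat = np.zeros((len(pairs), L), dtype=np.float32)
    tv_mat = np.zeros((len(pairs), L), dtype=np.float32)
    for k, (i, j) in enumerate(pairs):
        a, b = mat[i], mat[j]
        diff = a != b
        ts = diff & (((a + b) == 2) | ((a + b) == 4))
        ts_mat[k] = ts
        tv_mat[k] = diff & ~ts
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(L, np.full(L, 1.0 / L), size=n_reps).T.astype(
        np.float32
    )  # (L, n_reps) resample counts
    P = (ts_mat @ weights) / L  # (n_pairs, n_reps)
    Q = (tv_mat @ weights) / L

    counts: dict[int, int] = {}
    point_bitmasks = _internal_bitmasks(tree)
    for rep in range(n_reps):
        D = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            d = k2p_from_counts(float(P[k, rep]), float(Q[k, rep]))
            if math.isinf(d):
                d = SATURATION_CAP
            D[i, j] = D[j, i] = d
        rep_dm = DistanceMatrix(strains=strains, matrix=D, n_sites_used=L)
        rep_tree = nj_tree(rep_dm, outgroup=outgroup, taxon_namespace=tns)
        for bm in _internal_bitmasks(rep_tree):
            counts[bm] = counts.get(bm, 0) + 1

    tree.encode_bipartitions()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        bm = int(node.edge.bipartition.split_bitmask)
        node.label = f"{counts.get(bm, 0) / n_reps:.3f}"
    return tree


@dataclasses.dataclass(frozen=True)
class GroupTopology:
    """Strain tree collapsed to group-level leaves.

    ``canonical`` is a nested-tuple rooted topology with children sorted, so
    two topologies are congruent iff their canonical forms are equal.
    Paraphyletic groups appear as multiple leaves (suffixed ``g.1``, ``g.2``
    ... in the display newick) and are flagged in ``monophyletic``.
    """

    canonical: tuple
    newick: str
    monophyletic: Mapping[str, bool]

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, str):
                out.append(node)
            else:
                for c in node:
                    walk(c)

        walk(self.canonical)
        return tuple(sorted(out))


def group_topology(
    tree: dendropy.Tree, groups: Mapping[str, str]
) -> GroupTopology:
    """Collapse each maximal monophyletic same-group clade to one leaf.

    The tree must be rooted; every leaf's taxon label must have a group in
    ``groups``.  Unifurcations introduced by collapsing are suppressed.
    """
    missing = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in groups
    ]
    if missing:
        raise ValueError(f"leaves without group labels: {sorted(missing)}")

    clade_counts: dict[str, int] = {}

    def node_groups(node) -> set[str]:
        if node.is_leaf():
            return {groups[node.taxon.label]}
        out: set[str] = set()
        for c in node.child_nodes():
            out |= node_groups(c)
        return out

    def collapse(node):
        gs = node_groups(node)
        if len(gs) == 1:
            g = gs.pop()
            clade_counts[g] = clade_counts.get(g, 0) + 1
            return g  # leaf of the collapsed tree
        children = [collapse(c) for c in node.child_nodes()]
        if len(children) == 1:
            return children[0]
        return tuple(sorted(children, key=_canon_key))

    canonical = collapse(tree.seed_node)
    if isinstance(canonical, str):
        canonical = (canonical,)
    monophyletic = {g: n == 1 for g, n in clade_counts.items()}
    newick = _to_newick(canonical, clade_counts) + ";"
    return GroupTopology(
        canonical=canonical, newick=newick, monophyletic=monophyletic
    )


def _canon_key(node):
    return repr(node)


def _to_newick(node, clade_counts, seen=None) -> str:
    if seen is None:
        seen = {}
    if isinstance(node, str):
        if clade_counts.get(node, 1) > 1:
            seen[node] = seen.get(node, 0) + 1
            return f"{node}.{seen[node]}"
        return node
    return "(" + ",".join(_to_newick(c, clade_counts, seen) for c in node) + ")"


def congruent(t1: GroupTopology, t2: GroupTopology) -> bool:
    """Rooted-topology identity of two collapsed group trees."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError(
            f"group-leaf multisets differ: {t1.leaf_labels} vs {t2.leaf_labels}"
        )
    return t1.canonical == t2.canonical


def read_tree(path, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        taxon_namespace=taxon_namespace,
        rooting="force-rooted",
        preserve_underscores=True,
    )


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
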