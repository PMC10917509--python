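"""BIONJ tree building, outgroup rooting, Newick I/O and tree comparison.

The agglomeration implements the variance-weighted neighbor-joining of
Gascuel's BIONJ: at each step the pair minimizing the standard NJ Q
criterion is joined, branch lengths follow the NJ formulae, and the reduced
distances are a variance-weighted convex combination of the two joined
rows (lambda chosen to minimize the variance of the new row). On additive
matrices this reduces exactly to NJ and recovers the generating tree.

Trees are dendropy objects throughout; Newick serialization, rerooting and
Robinson-Foulds bipartition counting delegate to dendropy.
"""

from __future__ import annotations

import numpy as np
import dendropy
from dendropy.calculate import treecompare

from .metric import DistanceMatrix

Tree = dendropy.Tree


def bionj_tree(m: DistanceMatrix) -> Tree:
    """Build an unrooted BIONJ tree from a distance matrix.

    Deterministic: agglomeration ties on the Q criterion are broken by the
    lexicographically smallest pair of cluster representative labels.
    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.
    """
    D0 = np.asarray(m.values, dtype=float)
    n = len(m.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(D0)):
        raise ValueError("distance matrix contains NaN/inf")
    if not np.allclose(D0, D0.T) or not np.allclose(np.diag(D0), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")

    tns = dendropy.TaxonNamespace(m.labels)
    nodes = []
    for lab in m.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    # representative label of each active cluster, for deterministic ties
    reps = list(m.labels)
    d = {(i, j): D0[i, j] for i in range(n) for j in range(n) if i != j}
    v = dict(d)  # initial variances equal distances
    active = list(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j)] if i != j else 0.0

    while len(active) > 3:
        r = len(active)
        R = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist(i, j) - R[i] - R[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        bi = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        vij = v[(i, j)]
        if vij > 0:
            lam = 0.5 + sum(
                v[(j, k)] - v[(i, k)] for k in active if k not in (i, j)
            ) / (2.0 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = max(bi, 0.0)
        u.add_child(nodes[j])
        nodes[j].edge.length = max(bj, 0.0)
        nodes.append(u)
        reps.append(min(reps[i], reps[j]))

        for k in active:
            if k in (i, j):
                continue
            duk = lam * (dist(i, k) - bi) + (1 - lam) * (dist(j, k) - bj)
            vuk = lam * v[(i, k)] + (1 - lam) * v[(j, k)] - lam * (1 - lam) * vij
            d[(next_id, k)] = d[(k, next_id)] = duk
            v[(next_id, k)] = v[(k, next_id)] = vuk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    center = dendropy.Node()
    ba = (dist(a, b) + dist(a, c) - dist(b, c)) / 2.0
    bb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2.0
    bc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2.0
    for node_id, bl in ((a, ba), (b, bb), (c, bc)):
        center.add_child(nodes[node_id])
        nodes[node_id].edge.length = max(bl, 0.0)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def root_on_outgroup(t: Tree, outgroup: str) -> Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge."""
    t = t.clone(depth=1)
    leaf = None
    for nd in t.leaf_node_iter():
        if nd.taxon is not None and nd.taxon.label == outgroup:
            leaf = nd
            break
    if leaf is None:
        available = sorted(
            nd.taxon.label for nd in t.leaf_node_iter() if nd.taxon
        )
        raise ValueError(f"outgroup {outgroup!r} not a leaf; leaves: {available}")
    L = leaf.edge.length or 0.0
    t.reroot_at_edge(leaf.edge, length1=L / 2.0, length2=L / 2.0)
    t.is_rooted = True
    return t


def write_newick(t: Tree, path) -> None:
    """Serialize a tree as Newick with branch lengths at 6 decimals."""
    with open(path, "w") as fh:
        fh.write(
            t.as_string(
                schema="newick",
                real_value_format_specifier=".6f",
                suppress_rooting=True,
            )
        )


def read_newick(path) -> Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as e:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {e}") from e


def _common_namespace(t1: Tree, t2: Tree) -> tuple[Tree, Tree]:
    tns = dendropy.TaxonNamespace()
    s1 = t1.as_string(schema="newick")
    s2 = t2.as_string(schema="newick")
    c1 = dendropy.Tree.get(data=s1, schema="newick", taxon_namespace=tns)
    c2 = dendropy.Tree.get(data=s2, schema="newick", taxon_namespace=tns)
    return c1, c2


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Number of bipartitions present in exactly one of the two trees."""
    l1 = {nd.taxon.label for nd in t1.leaf_node_iter() if nd.taxon}
    l2 = {nd.taxon.label for nd in t2.leaf_node_iter() if nd.taxon}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    c1, c2 = _common_namespace(t1, t2)
    for c in (c1, c2):  # compare as unrooted topologies
        c.is_rooted = False
        if len(c.seed_node.child_nodes()) == 2:
            c.deroot()
        c.encode_bipartitions()
    return int(treecompare.symmetric_difference(c1, c2))


def normalized_rf(t1: Tree, t2: Tree) -> float:
    """Robinson-Foulds distance divided by its maximum 2(n-3)."""
    n = sum(1 for _ in t1.leaf_node_iter())
    denom = 2 * (n - 3)
    if denom <= 0:
        return 0.0
    return robinson_foulds(t1, t2) / denom


def leaf_path_distance(t: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    pdm = t.phylogenetic_distance_matrix()
    ta = t.taxon_namespace.get_taxon(a)
    tb = t.taxon_namespace.get_taxon(b)
    if ta is None or tb is None:
        raise ValueError("leaf label not in tree")
    return float(pdm.patristic_distance(ta, tb))
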