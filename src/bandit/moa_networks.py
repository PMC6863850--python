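"""Mechanism-of-action clustering and shared-target networks.

The pairwise TLR converts to a distance (distance = 1/TLR): drug pairs with
strong shared-target evidence sit close together. Average-linkage
agglomeration of that distance recovers mechanism groupings (e.g.
microtubule stabilizers vs destabilizers cluster apart even though both
bind tubulin); a shared-target network at a TLR cutoff places orphan
molecules next to the annotated drugs whose targets they are predicted to
share; classical multidimensional scaling embeds the whole drug universe.

The agglomeration is implemented here rather than delegated: dendrograms
must be deterministic (ties broken by lexical order of cluster member IDs)
and exportable as Newick with merge heights. Undefined TLRs inside a
clustering set are a hard error — silently imputing a distance would
fabricate mechanism structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import TargetTable


def tlr_to_distance(tlr: float) -> float:
    """Distance between two drugs: the reciprocal of their TLR."""
    if tlr <= 0:
        raise ValueError("TLR must be positive")
    return 1.0 / tlr


@dataclass
class DistanceMatrix:
    """Symmetric positive drug x drug distances (1/TLR)."""

    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.drug_ids)
        assert self.values.shape == (n, n)

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.drug_ids.index(a),
                                 self.drug_ids.index(b)])


def distance_matrix_from_tlrs(drug_ids: list[str],
                              tlrs: dict[tuple[str, str], float]
                              ) -> DistanceMatrix:
    """Build the complete 1/TLR distance matrix over ``drug_ids``,
    naming every missing pair in the error if the TLRs are incomplete."""
    n = len(drug_ids)
    values = np.zeros((n, n))
    missing = []
    for i, j in itertools.combinations(range(n), 2):
        key = tuple(sorted((drug_ids[i], drug_ids[j])))
        tlr = tlrs.get(key)
        if tlr is None:
            missing.append(key)
            continue
        d = tlr_to_distance(tlr)
        values[i, j] = values[j, i] = d
    if missing:
        raise ValueError(
            f"no TLR for {len(missing)} pair(s): {missing[:10]}"
            + (" ..." if len(missing) > 10 else ""))
    return DistanceMatrix(drug_ids=list(drug_ids), values=values)


@dataclass
class DendrogramNode:
    """Binary merge tree; leaves carry drug IDs, internal nodes heights."""

    members: tuple[str, ...]
    height: float = 0.0
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def moa_dendrogram(distances: DistanceMatrix,
                   linkage: str = "average") -> DendrogramNode:
    """Average-linkage (UPGMA-style) agglomeration of a complete distance
    matrix.

    At each step the pair of clusters with the smallest average inter-
    cluster distance merges at that distance; ties break on the lexically
    smallest (members_a, members_b) key, so the dendrogram is deterministic.
    O(n^3), fine for the few hundred drugs a mechanism set holds.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    ids = distances.drug_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 drugs to cluster")
    if not np.allclose(distances.values, distances.values.T):
        raise ValueError("distance matrix must be symmetric")
    off_diag = distances.values[~np.eye(n, dtype=bool)]
    if np.any(off_diag <= 0):
        raise ValueError("distances must be positive off the diagonal")

    nodes: dict[tuple[str, ...], DendrogramNode] = {
        (d,): DendrogramNode(members=(d,)) for d in ids}
    sizes = {(d,): 1 for d in ids}
    idx = {d: i for i, d in enumerate(ids)}
    # pairwise total distance between clusters (average = total / (na*nb))
    totals: dict[frozenset, float] = {}
    keys = sorted(nodes)
    for a, b in itertools.combinations(keys, 2):
        totals[frozenset((a, b))] = distances.values[idx[a[0]], idx[b[0]]]

    while len(nodes) > 1:
        best = None
        for a, b in itertools.combinations(sorted(nodes), 2):
            avg = totals[frozenset((a, b))] / (sizes[a] * sizes[b])
            key = (avg, tuple(sorted((a, b))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _), a, b = best
        merged_members = tuple(sorted(a + b))
        merged = DendrogramNode(members=merged_members, height=avg,
                                left=nodes[a], right=nodes[b])
        for other in list(nodes):
            if other in (a, b):
                continue
            totals[frozenset((merged_members, other))] = (
                totals.pop(frozenset((a, other)))
                + totals.pop(frozenset((b, other))))
        totals.pop(frozenset((a, b)))
        del nodes[a], nodes[b]
        nodes[merged_members] = merged
        sizes[merged_members] = sizes.pop(a) + sizes.pop(b)
    return next(iter(nodes.values()))


def cut_dendrogram(root: DendrogramNode, k: int) -> dict[str, int]:
    """Cluster labels from cutting the tree into k clusters (undo the last
    k-1 merges). Labels are arbitrary but deterministic integers."""
    if k < 1:
        raise ValueError("k must be >= 1")
    clusters = [root]
    while len(clusters) < k:
        tallest = max(range(len(clusters)),
                      key=lambda i: (clusters[i].height, clusters[i].members))
        node = clusters.pop(tallest)
        if node.is_leaf:
            raise ValueError(f"cannot cut into {k} clusters: too few leaves")
        clusters.extend([node.left, node.right])
    clusters.sort(key=lambda c: c.members)
    return {m: label for label, c in enumerate(clusters) for m in c.members}


def to_newick(root: DendrogramNode) -> str:
    """Newick string with branch lengths (parent height - child height)."""

    def walk(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.members[0]}:{length:.17g}"
        inner = f"({walk(node.left, node.height)},{walk(node.right, node.height)})"
        return f"{inner}:{length:.17g}"

    left = walk(root.left, root.height)
    right = walk(root.right, root.height)
    return f"({left},{right});"


def shared_target_network(tlrs: dict[tuple[str, str], float],
                          targets: TargetTable,
                          cutoff: float = 500.0,
                          min_known_edges: int = 2,
                          annotations: dict[str, dict] | None = None
                          ) -> nx.Graph:
    """Predicted shared-target network at a TLR cutoff.

    Edges are pairs with TLR >= cutoff, weighted by the TLR. Annotated
    drugs (known targets) always keep their qualifying edges; an orphan
    node is retained only when it connects to at least ``min_known_edges``
    annotated drugs — the stringency used for nominating new members of a
    target class. ``annotations`` supplies extra node attributes (e.g.
    atc_code).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    g = nx.Graph()
    for (a, b), tlr in tlrs.items():
        if a == b or tlr < cutoff:
            continue
        g.add_edge(a, b, tlr=float(tlr))
    # prune under-connected orphans (iterate: removing one can orphan another)
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            known = targets.get(node)
            if known:
                continue
            n_known_edges = sum(1 for nb in g.neighbors(node) if targets.get(nb))
            if n_known_edges < min_known_edges:
                g.remove_node(node)
                changed = True
    for node in g.nodes:
        known = targets.get(node)
        g.nodes[node]["is_orphan"] = not bool(known)
        g.nodes[node]["n_edges"] = g.degree(node)
        if annotations and node in annotations:
            g.nodes[node].update(annotations[node])
    return g


def universe_mds(distances: DistanceMatrix, dims: int = 2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of the drug universe.

    Double-centers the squared distance matrix and embeds on the top
    eigenvectors, the direct analogue of R's cmdscale. Returns
    (coordinates [n x dims], full eigenvalue spectrum descending).
    Components with non-positive eigenvalues embed as zeros.
    """
    d = distances.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    coords = np.zeros((n, dims))
    for a in range(min(dims, n)):
        if eigvals[a] > 1e-12:
            coords[:, a] = eigvecs[:, a] * np.sqrt(eigvals[a])
    return coords, eigvals
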