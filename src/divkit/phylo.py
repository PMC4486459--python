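"""Neighbor-joining trees, bootstrap clade support, and anchored clade
extraction.

The NJ implementation is the Saitou–Nei agglomeration with a fixed tie rule
(lowest-index pair on equal Q) so that a given matrix always yields the same
tree; negative branch lengths are clamped to zero and flagged, the common
distance-software convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .distance import DistanceMatrix, mcl_distances


def build_nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining. Returns an unrooted dendropy tree whose
    ``clamped_edges`` attribute lists leaf-pair joins where a negative branch
    length was clamped to 0."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    D = dm.d.copy()
    bad = ~np.isfinite(D)
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite distance between {dm.labels[i]!r} and {dm.labels[j]!r}")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    active = list(range(n))
    clamped = []

    def clamp(x, a, b):
        if x < 0:
            clamped.append((a, b))
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = np.array([sum(D[i, k] for k in active if k != i) for i in active])
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = 0.5 * D[i, j] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = D[i, j] - li
        li = clamp(li, dm.labels[i] if i < n else i, j)
        lj = clamp(lj, dm.labels[j] if j < n else j, i)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        D = np.pad(D, ((0, 1), (0, 1)))
        new = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    center = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        center.add_child(nodes[a])
        nodes[a].edge.length = clamp(la, a, b)
    tree.seed_node = center
    tree.clamped_edges = clamped
    tree.is_rooted = False
    return tree


def bootstrap_support(aln, reps: int, seed: int = 0, bootstrap_reps_distance: int = 0) -> dendropy.Tree:
    """NJ tree with bipartition supports (%) from ``reps`` site-resampling
    replicates. On a degenerate alignment (all pairwise distances zero) the
    topology is arbitrary; supports are set to 0 and ``degenerate`` flagged."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    dm = mcl_distances(aln, bootstrap_reps=0)
    main = build_nj_tree(dm)
    main.degenerate = bool(np.all(dm.d[np.triu_indices(len(dm.labels), 1)] == 0))

    rng = np.random.default_rng(seed)
    L = aln.length
    counts: dict[frozenset, int] = {}
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        rep_aln = aln.columns(cols)
        rep_dm = mcl_distances(rep_aln, bootstrap_reps=0)
        try:
            rep_tree = build_nj_tree(rep_dm)
        except ValueError:
            continue  # saturated replicate
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1

    main.bipartition_support = (
        {} if main.degenerate else {bp: 100.0 * c / reps for bp, c in counts.items()}
    )
    for node in main.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node.parent_node is None:
            continue
        bp = _bipartition_of(node, set(dm.labels))
        if bp is None:
            continue
        node.support = main.bipartition_support.get(bp, 0.0)
        node.label = f"{node.support:.0f}"
    return main


def find_mrca(tree: dendropy.Tree, names) -> dendropy.Node:
    """MRCA by walking rootward from one target leaf; robust to rerooted
    trees whose cached bipartition encodings are stale."""
    target = set(names)
    node = tree.find_node_with_taxon_label(sorted(target)[0])
    while node is not None:
        under = {lf.taxon.label for lf in node.leaf_iter()}
        if target <= under:
            return node
        node = node.parent_node
    raise ValueError(f"no common ancestor for {sorted(target)}")


def _bipartition_of(node, all_labels: set[str]):
    side = frozenset(lf.taxon.label for lf in node.leaf_iter())
    other = frozenset(all_labels - side)
    if len(side) < 2 or len(other) < 2:
        return None
    return min(side, other, key=sorted)


def _bipartitions(tree):
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        bp = _bipartition_of(node, labels)
        if bp is not None:
            out.add(bp)
    return out


def cut_into_clusters(tree: dendropy.Tree, k: int) -> list[set[str]]:
    """Partition the leaves into ``k`` clusters by removing the ``k - 1``
    longest internal edges (the deepest splits of a tree whose clusters are
    separated by long stems). Returns leaf-name sets, largest first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    work = tree.clone(depth=1)
    internal = [
        e
        for e in work.preorder_edge_iter()
        if e.head_node.parent_node is not None and not e.head_node.is_leaf()
    ]
    internal.sort(key=lambda e: (-(e.length or 0.0), min(lf.taxon.label for lf in e.head_node.leaf_iter())))
    cut = set()
    for e in internal[: k - 1]:
        cut.add(id(e.head_node))

    clusters: list[set[str]] = []

    def collect(node, bucket: set[str]):
        for child in node.child_nodes():
            if id(child) in cut:
                fresh: set[str] = set()
                clusters.append(fresh)
                collect(child, fresh)
            else:
                if child.is_leaf():
                    bucket.add(child.taxon.label)
                collect(child, bucket)

    first: set[str] = set()
    clusters.append(first)
    root = work.seed_node
    if root.is_leaf():
        first.add(root.taxon.label)
    collect(root, first)
    clusters = [c for c in clusters if c]
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


@dataclass
class CladeAssignment:
    assignment: dict[str, str]  # sequence name -> cluster label ("unassigned" allowed)
    support: dict[str, float | None] = field(default_factory=dict)  # cluster -> defining-edge support

    def members(self, label: str) -> set[str]:
        return {s for s, l in self.assignment.items() if l == label}


def extract_clades(
    tree: dendropy.Tree,
    anchors: dict[str, list[str]],
    min_support: float = 70.0,
    outgroup: str | None = None,
) -> CladeAssignment:
    """Assign every leaf to the smallest well-supported clade containing the
    anchors of each cluster label.

    A "clade" here is a split side of the (possibly unrooted) tree, so the
    result does not depend on an arbitrary rooting: for each cluster the
    smallest side, over all tree bipartitions with support >= ``min_support``
    (splits without a recorded support count as supported), that contains all
    of its anchors — and excludes ``outgroup`` if one is named. Overlapping
    cluster clades raise an error.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for label, names in anchors.items():
        for s in names:
            if s not in leaf_labels:
                raise ValueError(f"anchor {s!r} for cluster {label!r} not in tree")
    if outgroup is not None and outgroup not in leaf_labels:
        raise ValueError(f"outgroup {outgroup!r} not in tree")

    support_map = getattr(tree, "bipartition_support", None)
    if support_map is None:
        support_map = {}
        for node in tree.preorder_node_iter():
            sup = getattr(node, "support", None)
            if sup is None and node.label is not None and not node.is_leaf():
                try:
                    sup = float(node.label)
                except ValueError:
                    sup = None
            if node.is_leaf() or node.parent_node is None or sup is None:
                continue
            bp = _bipartition_of(node, leaf_labels)
            if bp is not None:
                support_map[bp] = sup

    # candidate sides: for every edge, the side of its split; plus the full set
    candidates: list[tuple[frozenset, float | None]] = [(frozenset(leaf_labels), None)]
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = frozenset(leaf_labels - side)
        bp = _bipartition_of(node, leaf_labels)
        sup = None if bp is None else support_map.get(bp, 0.0)
        for s in (side, other):
            if s:
                candidates.append((s, sup))

    clades: dict[str, set[str]] = {}
    supports: dict[str, float | None] = {}
    for label, names in anchors.items():
        need = set(names)
        viable = [
            (s, sup)
            for s, sup in candidates
            if need <= s
            and (outgroup is None or outgroup not in s or s == frozenset(leaf_labels))
            and (sup is None or sup >= min_support)
        ]
        best = min(viable, key=lambda c: (len(c[0]), sorted(c[0])))
        clades[label] = set(best[0])
        supports[label] = best[1]

    labels_sorted = sorted(clades)
    for a_i, a in enumerate(labels_sorted):
        for b in labels_sorted[a_i + 1 :]:
            if clades[a] & clades[b]:
                raise ValueError(f"clusters {a!r} and {b!r} resolve to overlapping clades")

    assignment = {}
    for leaf in leaf_labels:
        assignment[leaf] = "unassigned"
        for label in labels_sorted:
            if leaf in clades[label]:
                assignment[leaf] = label
                break
    return CladeAssignment(assignment, supports)
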