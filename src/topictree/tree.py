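"""Cell-cell distances, spanning trees, rooting and cell orderings.

Cells are compared through their topic histograms theta_d with the
chi-square histogram distance

    chi(x, y) = sqrt( sum_k (x_k - y_k)^2 / (x_k + y_k) )

(a summand with x_k + y_k = 0 contributes nothing).  A minimum spanning
tree over the distance matrix gives the population structure; the tree is
rooted either at an endpoint of its weighted diameter path (linear
processes) or at the most central cell of a designated starting group
(branching processes).  Cells are ordered by weighted path distance from
the root, a pseudotime proxy, and orderings are scored by pairwise
agreement with a reference ordering.  A travelling-salesman tour over the
raw distances serves as a naive baseline ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .lda import TopicModel


@dataclass
class CellDistanceMatrix:
    """Symmetric matrix of pairwise cell distances with zero diagonal."""

    d: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.cell_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match cell_ids")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0) or not np.allclose(self.d, self.d.T):
            raise ValueError("distances must be symmetric and non-negative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def index(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_cells, k=1)
        return self.d[iu]


@dataclass
class CellTree:
    """A spanning tree over cells; ``root`` may be unset until rooted."""

    edges: list[tuple[str, str, float]]
    cell_ids: list[str]
    root: str | None = None
    kind: str = "mst"

    def __post_init__(self) -> None:
        g = self.graph()
        if len(self.cell_ids) > 0:
            if g.number_of_nodes() != len(self.cell_ids) or \
               g.number_of_edges() != len(self.cell_ids) - 1 or \
               not nx.is_connected(g):
                raise ValueError("edges do not form a spanning tree")
        if self.root is not None and self.root not in self.cell_ids:
            raise ValueError("root is not a vertex of the tree")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cell_ids)
        g.add_weighted_edges_from(self.edges)
        return g

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def chi_square_distance(x, y) -> float:
    """Chi-square distance between two non-negative histograms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("histograms must be 1-D and the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("histogram entries must be non-negative")
    s = x + y
    diff2 = (x - y) ** 2
    terms = np.divide(diff2, s, out=np.zeros_like(s), where=s > 0)
    return float(np.sqrt(terms.sum()))


def distance_matrix(m: TopicModel) -> CellDistanceMatrix:
    """Pairwise chi-square distances between all cells' topic histograms."""
    t = m.theta
    # vectorised chi-square over all pairs; zero-sum components contribute 0
    s = t[:, None, :] + t[None, :, :]
    diff2 = (t[:, None, :] - t[None, :, :]) ** 2
    terms = np.divide(diff2, s, out=np.zeros_like(s), where=s > 0)
    d = np.sqrt(terms.sum(axis=2))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return CellDistanceMatrix(d, list(m.cell_ids))


# ---------------------------------------------------------------------------
# Minimum spanning tree (deterministic lexicographic Kruskal)
# ---------------------------------------------------------------------------

def minimum_spanning_tree(dm: CellDistanceMatrix) -> CellTree:
    """Kruskal MST with ties broken by lexicographic edge order."""
    n = dm.n_cells
    ids = dm.cell_ids
    order = sorted(range(n), key=lambda i: ids[i])
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            edges.append((float(dm.d[i, j]), ids[i], ids[j]))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    parent = {c: c for c in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges: list[tuple[str, str, float]] = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree_edges.append((u, v, w))
            if len(tree_edges) == n - 1:
                break
    return CellTree(tree_edges, list(ids))


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _check_start_group(cell_ids, start_group):
    sg = set(start_group)
    if not sg:
        raise ValueError("start group is empty")
    unknown = sg - set(cell_ids)
    if unknown:
        raise KeyError(f"start group names unknown cells: {sorted(unknown)}")
    return sg


def tree_diameter_path(t: CellTree) -> tuple[list[str], float]:
    """The weighted longest shortest path (diameter) of the tree.

    Double-sweep: farthest vertex from an arbitrary start, then farthest
    from that; exact on trees with non-negative weights.
    """
    g = t.graph()
    start = min(t.cell_ids)
    dist = nx.single_source_dijkstra_path_length(g, start)
    a = max(sorted(dist), key=lambda v: dist[v])
    dist_a, paths_a = nx.single_source_dijkstra(g, a)
    b = max(sorted(dist_a), key=lambda v: dist_a[v])
    return paths_a[b], float(dist_a[b])


def root_by_diameter(t: CellTree, dm: CellDistanceMatrix,
                     start_group) -> CellTree:
    """Root at the diameter endpoint closer (mean distance) to the start group."""
    sg = _check_start_group(t.cell_ids, start_group)
    path, _ = tree_diameter_path(t)
    a, b = path[0], path[-1]
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    g_idx = [idx[c] for c in sorted(sg)]

    def mean_to_group(v):
        return float(np.mean([dm.d[idx[v], j] for j in g_idx]))

    candidates = sorted([a, b])
    root = min(candidates, key=lambda v: (mean_to_group(v), v))
    return CellTree(list(t.edges), list(t.cell_ids), root=root, kind=t.kind)


def root_by_centrality(dm: CellDistanceMatrix, start_group) -> str:
    """Most central start-group cell: argmin mean squared distance to the rest."""
    sg = sorted(_check_start_group(dm.cell_ids, start_group))
    if len(sg) == 1:
        return sg[0]
    idx = {c: i for i, c in enumerate(dm.cell_ids)}

    def mean_sq(g):
        others = [idx[h] for h in sg if h != g]
        return float(np.mean(dm.d[idx[g], others] ** 2))

    return min(sg, key=lambda g: (mean_sq(g), g))


def set_root(t: CellTree, root: str) -> CellTree:
    return CellTree(list(t.edges), list(t.cell_ids), root=root, kind=t.kind)


def detect_start_group(dm: CellDistanceMatrix, groups: dict[str, str],
                       squared: bool = False) -> str:
    """Group with the lowest mean pairwise intra-group distance.

    Early developmental stages are typically the most homogeneous, so the
    tightest group is taken as the starting point.
    """
    labels = sorted(set(groups[c] for c in dm.cell_ids))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    means = {}
    for lab in labels:
        members = [idx[c] for c in dm.cell_ids if groups[c] == lab]
        if len(members) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
        sub = dm.d[np.ix_(members, members)]
        vals = sub[np.triu_indices(len(members), k=1)]
        if squared:
            vals = vals ** 2
        means[lab] = float(vals.mean())
    return min(labels, key=lambda l: (means[l], l))


# ---------------------------------------------------------------------------
# Orderings and their evaluation
# ---------------------------------------------------------------------------

def ordering_from_tree(t: CellTree) -> list[str]:
    """Cells by weighted path distance from the root (pseudotime proxy)."""
    if t.root is None:
        raise ValueError("tree is not rooted")
    dist = nx.single_source_dijkstra_path_length(t.graph(), t.root)
    return sorted(t.cell_ids, key=lambda c: (dist[c], c))


def pseudotime_from_tree(t: CellTree) -> dict[str, float]:
    if t.root is None:
        raise ValueError("tree is not rooted")
    return {c: float(v) for c, v in
            nx.single_source_dijkstra_path_length(t.graph(), t.root).items()}


def pairwise_ordering_accuracy(candidate: list[str], truth: list[str],
                               truth_ranks: dict[str, float] | None = None
                               ) -> float:
    """Percent of comparable cell pairs ordered consistently with the truth.

    ``truth_ranks`` may assign tied ranks (cells sharing a stage label);
    tied pairs are excluded from the denominator.  The candidate is reversed
    when that raises the score, since an ordering's direction is arbitrary.
    """
    if set(candidate) != set(truth):
        raise ValueError("candidate and truth must contain the same cells")
    if truth_ranks is None:
        truth_ranks = {c: float(i) for i, c in enumerate(truth)}
    n = len(candidate)
    cand_rank = {c: i for i, c in enumerate(candidate)}
    cells = list(truth)
    agree = comparable = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cells[i], cells[j]
            ta, tb = truth_ranks[a], truth_ranks[b]
            if ta == tb:
                continue
            comparable += 1
            if (ta < tb) == (cand_rank[a] < cand_rank[b]):
                agree += 1
    if comparable == 0:
        raise ValueError("no comparable pairs in the truth ordering")
    acc = 100.0 * agree / comparable
    return max(acc, 100.0 - acc)  # reversal rule


# ---------------------------------------------------------------------------
# TSP baseline
# ---------------------------------------------------------------------------

def tsp_baseline_ordering(dm: CellDistanceMatrix, start_group,
                          seed: int = 0) -> list[str]:
    """Nearest-neighbour + 2-opt open tour anchored in the start group.

    A naive ordering baseline: approximately minimises the total distance
    travelled when visiting every cell once.  The tour starts at the start
    group's most central cell, so no post-hoc shifting is needed; the
    construction is deterministic (``seed`` is accepted for interface
    stability but the algorithm has no random choices).
    """
    _check_start_group(dm.cell_ids, start_group)
    n = dm.n_cells
    d = dm.d
    if n == 1:
        return list(dm.cell_ids)

    # nearest-neighbour construction from the most central start-group cell
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    start = idx[root_by_centrality(dm, start_group)]
    tour = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        last = tour[-1]
        nxt = min(sorted(remaining), key=lambda j: (d[last, j], j))
        tour.append(nxt)
        remaining.discard(nxt)

    # 2-opt on the open path (first vertex pinned) until no improving swap
    improved = True
    while improved:
        improved = False
        for i in range(n - 2):
            for j in range(i + 1, n - 1):
                a, b = tour[i], tour[i + 1]
                c, e = tour[j], tour[j + 1]
                if d[a, c] + d[b, e] < d[a, b] + d[c, e] - 1e-15:
                    tour[i + 1:j + 1] = reversed(tour[i + 1:j + 1])
                    improved = True
    return [dm.cell_ids[i] for i in tour]


def tour_length(dm: CellDistanceMatrix, ordering: list[str]) -> float:
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    return float(sum(dm.d[idx[a], idx[b]]
                     for a, b in zip(ordering, ordering[1:])))


def euclidean_distance_matrix(values: np.ndarray,
                              cell_ids: list[str]) -> CellDistanceMatrix:
    """Euclidean distances between cell columns of an expression matrix."""
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(values.T))
    return CellDistanceMatrix(d, list(cell_ids))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def tree_to_dot(t: CellTree) -> str:
    lines = ["graph cells {"]
    if t.root is not None:
        lines.append(f'  "{t.root}" [root=true, shape=doublecircle];')
    for u, v, w in t.edges:
        lines.append(f'  "{u}" -- "{v}" [weight={w:.6g}, label="{w:.3g}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def tree_to_edge_tsv(t: CellTree) -> str:
    """3-column TSV (child, parent, weight); parent-child via the root."""
    if t.root is None:
        rows = [(u, v, w) for u, v, w in t.edges]
    else:
        g = t.graph()
        parent = {t.root: None}
        rows = []
        for u, v in nx.bfs_edges(g, t.root):
            rows.append((v, u, g[u][v]["weight"]))
    out = ["child\tparent\tweight"]
    for a, b, w in rows:
        out.append(f"{a}\t{b}\t{w:.10g}")
    return "\n".join(out) + "\n"


def ordering_to_tsv(ordering: list[str]) -> str:
    out = ["rank\tcell_id"]
    out += [f"{i}\t{c}" for i, c in enumerate(ordering)]
    return "\n".join(out) + "\n"
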