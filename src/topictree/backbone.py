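"""Backbone trees: compact representative subtrees of a cell population.

A backbone tree over cells V with distance d and width delta is a spanning
tree T whose vertices split into:

* a backbone B = (V_B, E_B), a subtree of T;
* "vertebrae": every remaining (non-outlier) vertex v sits within delta of
  the backbone and is attached by a single edge to its *closest* backbone
  vertex;
* at most a fixed fraction of outliers, exempt from the delta constraint.

The optimal backbone tree minimises the summed edge weights of its backbone
subtree — finding it is NP-complete, so construction uses an MST-based
leaf-absorption heuristic, with an exhaustive solver available for small
instances as an exact reference.

The width delta is estimated from the data as the first mode of the kernel
density estimate of the pairwise-distance distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .tree import CellDistanceMatrix, CellTree, minimum_spanning_tree, \
    root_by_centrality


class InfeasibleError(ValueError):
    """No valid backbone tree exists under the given delta / outlier budget."""


@dataclass
class BackboneTree:
    """Partition of cells into backbone vertices, vertebrae and outliers."""

    backbone_vertices: set[str]
    backbone_edges: list[tuple[str, str, float]]
    vertebra_attachments: dict[str, str]
    outliers: set[str]
    delta: float
    cell_ids: list[str]
    root: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vb = set(self.backbone_vertices)
        vert = set(self.vertebra_attachments)
        out = set(self.outliers)
        if vb | vert | out != set(self.cell_ids) or \
           (vb & vert) or (vb & out) or (vert & out):
            raise ValueError("backbone/vertebrae/outliers must partition the cells")
        if self.root is not None and self.root not in vb:
            raise ValueError("root must be a backbone vertex")

    @property
    def objective(self) -> float:
        """Sum of backbone edge weights (the quantity minimised)."""
        return float(sum(w for _, _, w in self.backbone_edges))

    def backbone_subtree(self) -> CellTree:
        return CellTree(list(self.backbone_edges), sorted(self.backbone_vertices),
                        root=self.root)

    def full_edges(self, dm: CellDistanceMatrix) -> list[tuple[str, str, float]]:
        idx = {c: i for i, c in enumerate(dm.cell_ids)}
        edges = list(self.backbone_edges)
        for v, b in sorted(self.vertebra_attachments.items()):
            edges.append((v, b, float(dm.d[idx[v], idx[b]])))
        return edges


# ---------------------------------------------------------------------------
# delta estimation
# ---------------------------------------------------------------------------

def estimate_delta(dm: CellDistanceMatrix, grid_points: int = 512,
                   bw_method: str = "silverman") -> tuple[float, dict]:
    """First mode of the KDE of pairwise distances.

    Returns ``(delta, info)``; ``info['fallback']`` is True when the density
    has no interior local maximum and the 25th percentile is used instead.
    """
    if dm.n_cells < 3:
        raise ValueError("need at least 3 cells (3 pairwise distances)")
    vals = dm.upper_triangle()
    if np.all(vals == 0):
        raise ValueError("all pairwise distances are zero")
    kde = gaussian_kde(vals, bw_method=bw_method)
    grid = np.linspace(0.0, float(vals.max()), grid_points)
    dens = kde(grid)
    mode = _first_mode(grid, dens)
    if mode is not None:
        return mode, {"fallback": False, "grid": grid, "density": dens}
    delta = float(np.percentile(vals, 25))
    return delta, {"fallback": True, "grid": grid, "density": dens}


def _first_mode(grid: np.ndarray, dens: np.ndarray) -> float | None:
    """Smallest grid point that is a strict interior local maximum."""
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    modes = np.nonzero(interior)[0] + 1
    if modes.size:
        return float(grid[modes[0]])
    return None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def check_backbone(t: BackboneTree, dm: CellDistanceMatrix,
                   outlier_fraction: float = 0.05) -> list[str]:
    """Report which of the defining conditions a candidate violates.

    1. backbone + vertebrae + outliers form a spanning structure (partition,
       backbone connected and acyclic);
    2. the backbone is a subtree (tree over its vertices);
    3. every vertebra lies within delta of some backbone vertex;
    4. every vertebra attaches by a single edge to its *closest* backbone
       vertex;
    plus the outlier budget.  Empty list means valid.
    """
    import networkx as nx
    violations = []
    vb = sorted(t.backbone_vertices)
    idx = {c: i for i, c in enumerate(dm.cell_ids)}

    g = nx.Graph()
    g.add_nodes_from(vb)
    g.add_weighted_edges_from(t.backbone_edges)
    if set(g.nodes) != set(vb) or g.number_of_edges() != len(vb) - 1 or \
            (len(vb) > 0 and not nx.is_connected(g)):
        violations.append("backbone is not a tree over its vertices")

    union = t.backbone_vertices | set(t.vertebra_attachments) | t.outliers
    if union != set(dm.cell_ids):
        violations.append("cells are not partitioned into roles")

    for v, b in sorted(t.vertebra_attachments.items()):
        if b not in t.backbone_vertices:
            violations.append(f"vertebra {v} attached to non-backbone vertex {b}")
            continue
        dv = dm.d[idx[v]]
        if dv[idx[b]] > t.delta + 1e-12:
            violations.append(f"vertebra {v} farther than delta from attachment")
        best = min(vb, key=lambda u: (dv[idx[u]], u))
        if dv[idx[best]] < dv[idx[b]] - 1e-12:
            violations.append(f"vertebra {v} not attached to its closest "
                              f"backbone vertex ({best})")

    if len(t.outliers) > outlier_fraction * len(dm.cell_ids) + 1e-9:
        violations.append("outlier budget exceeded")
    return violations


# ---------------------------------------------------------------------------
# Heuristic construction (MST leaf absorption)
# ---------------------------------------------------------------------------

def _mst_over(dm: CellDistanceMatrix, vertices: list[str]):
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    sub_idx = [idx[v] for v in vertices]
    sub = CellDistanceMatrix(dm.d[np.ix_(sub_idx, sub_idx)], list(vertices))
    return minimum_spanning_tree(sub)


def _attach_vertebrae(dm, backbone, others):
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    vb = sorted(backbone)
    return {v: min(vb, key=lambda u: (dm.d[idx[v], idx[u]], u)) for v in others}


def build_backbone(dm: CellDistanceMatrix, delta: float | None = None,
                   outlier_fraction: float = 0.05,
                   root_hint: str | None = None) -> BackboneTree:
    """Construct a backbone tree with the MST leaf-absorption heuristic.

    The full MST is pruned greedily: among current leaves, repeatedly remove
    the one hanging off the heaviest edge, provided it can be re-attached as
    a vertebra (within ``delta`` of some remaining vertex) or charged to the
    remaining outlier budget (absorption preferred over outlier).  What
    remains is the backbone; absorbed vertices attach to their closest
    backbone vertex.  The result always satisfies the backbone conditions
    and its objective never exceeds that of the all-backbone MST.

    Vertices farther than ``delta`` from every other vertex cannot be
    vertebrae; they are charged to the outlier budget first (most isolated
    first) and any excess remains in the backbone, which the definition
    always permits.
    """
    if not (0 <= outlier_fraction < 1):
        raise ValueError("outlier_fraction must be in [0, 1)")
    meta = {}
    if delta is None:
        delta, info = estimate_delta(dm)
        meta["delta_fallback"] = info["fallback"]
    if delta <= 0:
        raise ValueError("delta must be positive")
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    n = dm.n_cells
    budget = int(outlier_fraction * n)

    # vertices beyond delta of everything can never be vertebrae: charge
    # them to the outlier budget first (most isolated first); any left over
    # stay in the backbone, where the definition always admits them
    iso = []
    for v in sorted(dm.cell_ids):
        others = [u for u in dm.cell_ids if u != v]
        if others and min(dm.d[idx[v], idx[u]] for u in others) > delta:
            iso.append(v)
    iso.sort(key=lambda v: (-min(dm.d[idx[v], idx[u]]
                                 for u in dm.cell_ids if u != v), v))
    outliers: list[str] = list(iso[:budget])
    forced_backbone = set(iso[budget:])
    core = [c for c in dm.cell_ids if c not in set(outliers)]

    mst = _mst_over(dm, core) if len(core) > 1 else CellTree([], core)
    g = mst.graph()

    removed_vertebrae: list[str] = []
    alive = np.zeros(n, dtype=bool)
    alive[[idx[c] for c in core]] = True
    while g.number_of_nodes() > 1:
        leaves = [v for v in g.nodes
                  if g.degree(v) == 1 and v not in forced_backbone]
        # absorbable leaves: within delta of some remaining vertex, or
        # chargeable to the remaining outlier budget (vertebra preferred)
        best = None  # (edge weight, leaf, mode)
        for v in sorted(leaves):
            w = max(g[v][u]["weight"] for u in g[v])
            mask = alive.copy()
            mask[idx[v]] = False
            if (dm.d[idx[v]][mask] <= delta).any():
                mode = "vertebra"
            elif len(outliers) < budget:
                mode = "outlier"
            else:
                continue
            if best is None or w > best[0]:
                best = (w, v, mode)
        if best is None:
            break
        _, v, mode = best
        g.remove_node(v)
        alive[idx[v]] = False
        (removed_vertebrae if mode == "vertebra" else outliers).append(v)

    backbone = sorted(g.nodes)
    # a vertex absorbed early may have lost its nearby anchor later; restore
    # such stranded vertices to the backbone to keep the tree valid
    while True:
        stranded = [v for v in removed_vertebrae
                    if min(dm.d[idx[v], idx[u]] for u in backbone) > delta]
        if not stranded:
            break
        removed_vertebrae = [v for v in removed_vertebrae if v not in set(stranded)]
        backbone = sorted(set(backbone) | set(stranded))

    # local improvement on the backbone set: delete / swap / add moves are
    # accepted while the backbone MST gets lighter and coverage holds
    backbone = _improve_backbone(dm, backbone, outliers, forced_backbone, delta)
    non_out = [c for c in dm.cell_ids if c not in set(outliers)]
    vertebrae = [c for c in non_out if c not in set(backbone)]

    bb_tree = _mst_over(dm, backbone) if len(backbone) > 1 else \
        CellTree([], backbone)
    attachments = _attach_vertebrae(dm, backbone, vertebrae)
    t = BackboneTree(set(backbone), list(bb_tree.edges), attachments,
                     set(outliers), float(delta), list(dm.cell_ids), meta=meta)
    bad = check_backbone(t, dm, outlier_fraction)
    if bad:  # construction guarantees validity; guard against regressions
        raise AssertionError(f"heuristic produced an invalid backbone: {bad}")
    return t


def _improve_backbone(dm: CellDistanceMatrix, backbone: list[str],
                      outliers: list[str], forced_backbone: set[str],
                      delta: float) -> list[str]:
    """Steepest-descent local search over backbone vertex sets.

    Moves: drop a backbone vertex, swap one for an outside vertex, or add
    an outside vertex; a move is legal when every non-outlier stays within
    delta of the backbone, and accepted when the backbone MST over the
    candidate set is strictly lighter.  Weights use scipy's MST (total
    weight is tie-break independent).
    """
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    out_set = set(outliers)
    non_out = np.array([idx[c] for c in dm.cell_ids if c not in out_set])
    d = dm.d

    def mst_weight(vb_idx: np.ndarray) -> float:
        # Prim's algorithm; total weight does not depend on tie-breaking
        n = vb_idx.size
        if n <= 1:
            return 0.0
        D = d[np.ix_(vb_idx, vb_idx)]
        in_tree = np.zeros(n, dtype=bool)
        in_tree[0] = True
        mind = D[0].copy()
        mind[0] = np.inf
        total = 0.0
        for _ in range(n - 1):
            j = int(np.argmin(np.where(in_tree, np.inf, mind)))
            total += mind[j]
            in_tree[j] = True
            mind = np.minimum(mind, D[j])
            mind[j] = np.inf
        return float(total)

    def covered(vb_idx: np.ndarray) -> bool:
        rest = non_out[~np.isin(non_out, vb_idx, assume_unique=True)]
        if rest.size == 0:
            return True
        return bool((d[np.ix_(rest, vb_idx)].min(axis=1) <= delta).all())

    vb = np.array(sorted(idx[c] for c in backbone))
    forced = {idx[c] for c in forced_backbone}
    current = mst_weight(vb)
    for phase in ("delete", "full"):
        improved = True
        while improved:
            improved = False
            best: tuple[float, np.ndarray] | None = None
            removable = [v for v in vb if v not in forced]
            candidates = []
            if vb.size > 1:
                candidates += [vb[vb != v] for v in removable]
            if phase == "full":
                outside = non_out[~np.isin(non_out, vb)]
                candidates += [np.sort(np.append(vb[vb != v], u))
                               for v in removable for u in outside]
                candidates += [np.sort(np.append(vb, u)) for u in outside]
            for cand in candidates:
                if not covered(cand):
                    continue
                w = mst_weight(cand)
                if w < current - 1e-15 and (best is None or w < best[0]):
                    best = (w, cand)
            if best is not None:
                current, vb = best[0], best[1]
                improved = True
    return sorted(dm.cell_ids[i] for i in vb)


# ---------------------------------------------------------------------------
# Exact solver for small instances (reference/oracle)
# ---------------------------------------------------------------------------

def brute_force_backbone(dm: CellDistanceMatrix, delta: float,
                         outlier_fraction: float = 0.05,
                         max_cells: int = 10) -> BackboneTree:
    """Exhaustive minimum-objective backbone tree (instances of <= 10 cells).

    Enumerates every outlier set within budget and every backbone vertex
    subset of the rest, takes the MST over the backbone set as its subtree,
    keeps feasible candidates and returns the minimum objective (ties:
    smaller backbone, then lexicographic vertex list).
    """
    n = dm.n_cells
    if n > max_cells:
        raise ValueError(f"exact solver limited to {max_cells} cells")
    ids = sorted(dm.cell_ids)
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    budget = int(outlier_fraction * n)

    best = None  # (objective, |V_B|, vb tuple, tree)
    for n_out in range(budget + 1):
        for out in itertools.combinations(ids, n_out):
            rest = [c for c in ids if c not in out]
            for size in range(1, len(rest) + 1):
                for vb in itertools.combinations(rest, size):
                    vb_set = set(vb)
                    others = [c for c in rest if c not in vb_set]
                    # feasibility: all vertebrae within delta of backbone
                    feasible = all(
                        min(dm.d[idx[v], idx[u]] for u in vb) <= delta
                        for v in others)
                    if not feasible:
                        continue
                    sub = _mst_over(dm, list(vb)) if size > 1 else \
                        CellTree([], list(vb))
                    obj = sub.total_weight
                    key = (obj, size, vb)
                    if best is None or key < (best[0], best[1], best[2]):
                        att = _attach_vertebrae(dm, list(vb), others)
                        t = BackboneTree(vb_set, list(sub.edges), att,
                                         set(out), float(delta),
                                         list(dm.cell_ids))
                        best = (obj, size, vb, t)
    if best is None:
        raise InfeasibleError("no feasible backbone tree under this delta/budget")
    return best[3]


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_backbone(t: BackboneTree, dm: CellDistanceMatrix,
                  start_group) -> BackboneTree:
    """Root at the start group's most central cell, mapped into the backbone.

    If the central cell is itself a vertebra (or outlier), its closest
    backbone vertex becomes the root instead.
    """
    central = root_by_centrality(dm, start_group)
    if central in t.backbone_vertices:
        root = central
    elif central in t.vertebra_attachments:
        root = t.vertebra_attachments[central]
    else:
        idx = {c: i for i, c in enumerate(dm.cell_ids)}
        root = min(sorted(t.backbone_vertices),
                   key=lambda u: (dm.d[idx[central], idx[u]], u))
    return BackboneTree(set(t.backbone_vertices), list(t.backbone_edges),
                        dict(t.vertebra_attachments), set(t.outliers),
                        t.delta, list(t.cell_ids), root=root, meta=dict(t.meta))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def backbone_to_tsv(t: BackboneTree, dm: CellDistanceMatrix) -> str:
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    lines = ["cell_id\trole\tattachment\tdistance_to_attachment"]
    for c in dm.cell_ids:
        if c in t.backbone_vertices:
            lines.append(f"{c}\tbackbone\t\t0")
        elif c in t.vertebra_attachments:
            b = t.vertebra_attachments[c]
            lines.append(f"{c}\tvertebra\t{b}\t{dm.d[idx[c], idx[b]]:.10g}")
        else:
            lines.append(f"{c}\toutlier\t\t")
    return "\n".join(lines) + "\n"


def backbone_to_dot(t: BackboneTree, dm: CellDistanceMatrix) -> str:
    lines = ["graph backbone {"]
    for c in sorted(t.backbone_vertices):
        shape = "doublecircle" if c == t.root else "circle"
        lines.append(f'  "{c}" [role=backbone, shape={shape}, width=0.8];')
    for c in sorted(t.vertebra_attachments):
        lines.append(f'  "{c}" [role=vertebra, shape=point];')
    for c in sorted(t.outliers):
        lines.append(f'  "{c}" [role=outlier, shape=triangle];')
    for u, v, w in t.backbone_edges:
        lines.append(f'  "{u}" -- "{v}" [weight={w:.6g}, penwidth=2];')
    idx = {c: i for i, c in enumerate(dm.cell_ids)}
    for v, b in sorted(t.vertebra_attachments.items()):
        lines.append(f'  "{v}" -- "{b}" [weight={dm.d[idx[v], idx[b]]:.6g}, '
                     f'style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"
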