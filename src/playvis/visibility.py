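"""Cell-to-cell visibility graph and Visual Mean Depth (VMD).

Grid visibility-graph analysis: every walkable lattice cell is a node,
and two nodes are joined when the straight line between their centroids
is not interrupted by any obstruction polygon.  VMD of a cell is the
mean number of graph edges ("visual steps") on shortest paths from that
cell to every other cell of its connected component — 1 when everything
is directly visible, higher for visually deeper (more hidden) spots.

Line of sight is centroid-to-centroid.  A sight line that merely grazes
an obstruction edge or vertex (contact of measure zero, within an
epsilon of 1e-9 m) still counts as visible; only passage through an
obstruction's interior blocks.  The boundary itself never blocks sight —
cells outside it simply do not exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .geometry import GridLattice, PlaygroundLayout

logger = logging.getLogger("playvis")

#: Grazing tolerance in metres: intersections thinner than this do not block.
GRAZE_EPS = 1e-9


# ---------------------------------------------------------------------------
# Line-of-sight predicate
# ---------------------------------------------------------------------------

def intervisible(p, q, obstructions, eps: float = GRAZE_EPS) -> bool:
    """True iff the open segment p–q does not pass through any obstruction.

    Grazing contact with an obstruction edge or vertex does not block.
    The degenerate case ``p == q`` is visible by definition.
    """
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])
    if abs(px - qx) <= eps and abs(py - qy) <= eps:
        return True
    seg = LineString([(px, py), (qx, qy)])
    # blocked iff the segment's interior meets an obstruction's interior
    # along a 1-dimensional piece (grazing gives dimension 0 or F)
    return not any(seg.relate_pattern(obs, "1********") for obs in obstructions)


def _edges_of(poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    rings = [np.asarray(poly.exterior.coords)]
    rings += [np.asarray(r.coords) for r in poly.interiors]
    a = np.concatenate([r[:-1] for r in rings])
    b = np.concatenate([r[1:] for r in rings])
    return a, b


def _blocked_batch(
    starts: np.ndarray,
    ends: np.ndarray,
    obstructions: list[Polygon],
    tol: float = GRAZE_EPS,
) -> np.ndarray:
    """Vectorised blocked test for n segments against all obstructions.

    A segment is blocked when it properly crosses an obstruction edge
    (endpoints are outside the obstructions, so a proper boundary crossing
    means the segment enters the interior).  Near-degenerate contacts
    (segment through a vertex, endpoint on an edge) are re-checked with
    the exact per-pair predicate.
    """
    n = len(starts)
    blocked = np.zeros(n, dtype=bool)
    suspect = np.zeros(n, dtype=bool)
    rx = ends[:, 0] - starts[:, 0]
    ry = ends[:, 1] - starts[:, 1]
    seg_minx = np.minimum(starts[:, 0], ends[:, 0])
    seg_maxx = np.maximum(starts[:, 0], ends[:, 0])
    seg_miny = np.minimum(starts[:, 1], ends[:, 1])
    seg_maxy = np.maximum(starts[:, 1], ends[:, 1])

    for obs in obstructions:
        ominx, ominy, omaxx, omaxy = obs.bounds
        cand = ~(
            (seg_maxx < ominx - tol)
            | (seg_minx > omaxx + tol)
            | (seg_maxy < ominy - tol)
            | (seg_miny > omaxy + tol)
        )
        cand &= ~blocked
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        sx, sy = starts[idx, 0], starts[idx, 1]
        vx, vy = rx[idx], ry[idx]
        a, b = _edges_of(obs)
        for (ax, ay), (bx, by) in zip(a, b):
            # side of each edge endpoint w.r.t. the segment's line
            d1 = vx * (ay - sy) - vy * (ax - sx)
            d2 = vx * (by - sy) - vy * (bx - sx)
            ex, ey = bx - ax, by - ay
            # side of each segment endpoint w.r.t. the edge's line
            d3 = ex * (sy - ay) - ey * (sx - ax)
            d4 = ex * (sy + vy - ay) - ey * (sx + vx - ax)
            p12 = d1 * d2
            p34 = d3 * d4
            proper = (p12 < -tol) & (p34 < -tol)
            blocked[idx[proper]] = True
            near = (
                ~proper
                & (
                    ((np.minimum(np.abs(d1), np.abs(d2)) <= tol) & (p34 <= tol))
                    | ((np.minimum(np.abs(d3), np.abs(d4)) <= tol) & (p12 <= tol))
                )
            )
            suspect[idx[near]] = True

    recheck = np.flatnonzero(suspect & ~blocked)
    for i in recheck:
        blocked[i] = not intervisible(starts[i], ends[i], obstructions, eps=tol)
    return blocked


# ---------------------------------------------------------------------------
# Graph and VMD
# ---------------------------------------------------------------------------

@dataclass
class VisibilityGraph:
    """Intervisibility relation between walkable cells.

    ``node_index`` holds flat lattice indices of the nodes (walkable
    cells); ``adjacency`` is a dense symmetric boolean matrix with a
    False diagonal; ``component_id`` labels connected components.
    """

    node_index: np.ndarray
    points: np.ndarray
    adjacency: np.ndarray
    component_id: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degree(self) -> np.ndarray:
        """Node degree — the space-syntax 'connectivity' of each cell."""
        return self.adjacency.sum(axis=1)

    def component_sizes(self) -> np.ndarray:
        if self.n_nodes == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.component_id)


def build_visibility_graph(
    lattice: GridLattice, layout: PlaygroundLayout, chunk: int = 64
) -> VisibilityGraph:
    """Connect every pair of walkable cell centroids that can see each other.

    All unordered pairs are tested with the vectorised line-of-sight
    routine (bounding-box pruning per obstruction); the result is exactly
    the relation defined by :func:`intervisible`.
    """
    idx = lattice.walkable_indices()
    pts = np.column_stack([lattice.cx[idx], lattice.cy[idx]])
    n = len(idx)
    adj = np.zeros((n, n), dtype=bool)
    obstructions = list(layout.obstructions)
    if n:
        if not obstructions:
            adj[:] = True
        else:
            for s0 in range(0, n, chunk):
                s1 = min(s0 + chunk, n)
                # all pairs (i, j) with s0 <= i < s1 and j > i
                ii, jj = np.meshgrid(np.arange(s0, s1), np.arange(n), indexing="ij")
                keep = jj > ii
                ii, jj = ii[keep], jj[keep]
                if ii.size == 0:
                    continue
                blocked = _blocked_batch(pts[ii], pts[jj], obstructions)
                vis = ~blocked
                adj[ii[vis], jj[vis]] = True
                adj[jj[vis], ii[vis]] = True
        np.fill_diagonal(adj, False)

    if n:
        ncomp, comp = connected_components(sparse.csr_matrix(adj), directed=False)
    else:
        comp = np.zeros(0, dtype=int)
    return VisibilityGraph(node_index=idx, points=pts, adjacency=adj, component_id=comp)


@dataclass
class VMDField:
    """Per-cell Visual Mean Depth, aligned with a graph's node order.

    ``values[i]`` is NaN for nodes in singleton components.  ``coverage``
    reports component sizes and the fraction of nodes outside the largest
    component (downstream regression keeps only the largest component).
    """

    node_index: np.ndarray
    values: np.ndarray
    component_id: np.ndarray
    coverage: dict = field(default_factory=dict)

    def in_largest_component(self) -> np.ndarray:
        if len(self.component_id) == 0:
            return np.zeros(0, dtype=bool)
        sizes = np.bincount(self.component_id)
        return self.component_id == int(np.argmax(sizes))


def compute_vmd(graph: VisibilityGraph) -> VMDField:
    """Mean shortest-path edge count from each node to all others in its
    component (unweighted breadth-first distances).

    Distances are expanded wavefront-style with boolean matrix products,
    which is exact and fast for the small graph diameters typical of
    open layouts.  Singleton-component nodes get NaN.
    """
    n = graph.n_nodes
    if n == 0:
        return VMDField(graph.node_index, np.zeros(0), graph.component_id, {"components": []})
    A = graph.adjacency
    same_comp = graph.component_id[:, None] == graph.component_id[None, :]
    reach = A.copy()
    dist = np.where(A, 1, 0).astype(np.int32)
    Af = A.astype(np.float32)
    k = 1
    target = same_comp.copy()
    np.fill_diagonal(target, False)
    while (reach != target).any():
        newreach = (reach.astype(np.float32) @ Af) > 0
        newreach |= reach
        np.fill_diagonal(newreach, False)
        new = newreach & ~reach
        if not new.any():  # safety: disconnected remainder (should not happen)
            break
        k += 1
        dist[new] = k
        reach = newreach

    comp_sizes = np.bincount(graph.component_id)
    size_of = comp_sizes[graph.component_id]
    with np.errstate(invalid="ignore", divide="ignore"):
        vmd = dist.sum(axis=1) / (size_of - 1)
    vmd[size_of < 2] = np.nan

    largest = int(np.argmax(comp_sizes))
    coverage = {
        "n_nodes": int(n),
        "n_components": int(len(comp_sizes)),
        "component_sizes": comp_sizes.tolist(),
        "largest_component": largest,
        "fraction_outside_largest": float(1.0 - comp_sizes[largest] / n),
        "singleton_nodes": int((size_of < 2).sum()),
    }
    if coverage["fraction_outside_largest"] > 0:
        logger.info(
            "visibility graph has %d components; %.1f%% of cells outside the largest",
            coverage["n_components"],
            100 * coverage["fraction_outside_largest"],
        )
    return VMDField(graph.node_index, vmd, graph.component_id, coverage)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def vmd_frame(field: VMDField, lattice: GridLattice) -> pd.DataFrame:
    """Full-lattice table (row, col, cx, cy, zone, vmd); vmd is NaN for
    non-walkable cells and for cells without a defined VMD."""
    vmd_full = np.full(lattice.n_cells, np.nan)
    vmd_full[field.node_index] = field.values
    return pd.DataFrame(
        {
            "row": lattice.row,
            "col": lattice.col,
            "cx": lattice.cx,
            "cy": lattice.cy,
            "zone": lattice.zone_of,
            "vmd": vmd_full,
        }
    )


def export_vmd(field: VMDField, lattice: GridLattice, path, png_path=None) -> None:
    """Write the VMD field as CSV (and optionally render a raster PNG).

    Missing VMD values are written as empty fields, never as zero.
    """
    df = vmd_frame(field, lattice)
    df.to_csv(path, index=False, float_format="%.12g")
    if png_path is not None:
        render_vmd(field, lattice, png_path)


def read_vmd_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def render_vmd(field: VMDField, lattice: GridLattice, png_path) -> None:
    """Raster image of the field: low VMD dark, high VMD bright."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.full((lattice.nrows, lattice.ncols), np.nan)
    df = vmd_frame(field, lattice)
    img[df["row"], df["col"]] = df["vmd"]
    fig, ax = plt.subplots(figsize=(8, 8 * lattice.nrows / max(lattice.ncols, 1)))
    m = ax.imshow(img, origin="lower", cmap="viridis", interpolation="nearest")
    fig.colorbar(m, ax=ax, label="Visual Mean Depth")
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
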