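"""Ten-second movement trajectories and per-cell usage heatmaps.

Each observed child contributes one short polyline (their movement over
a 10-second observation window) tagged with school, apparent gender,
year group, activity and play type.  A 70 cm buffer around the polyline
represents the space a moving child occupies; the number of *distinct*
buffered trajectories overlapping each lattice cell, split by
demographic group, is the usage count that feeds the regression stage.

A trajectory increments a cell at most once, even when the path crosses
the cell repeatedly: counts are trajectory-level, not pass-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from .geometry import GridLattice
from .visibility import VMDField

logger = logging.getLogger("playvis")

GENDERS = ("male", "female")
YEAR_GROUPS = ("Y3/4", "Y5/6")
ACTIVITIES = ("play", "conversation", "other")
BALL_GAME = "ball game"

#: Segments per quarter circle used for buffer arcs.
BUFFER_QUAD_SEGS = 32
#: Intersections smaller than this (m^2) are numerical slivers, not touches.
TOUCH_AREA_EPS = 1e-6


@dataclass(frozen=True)
class TrajectoryRecord:
    """One observed 10-second movement polyline with its attributes."""

    id: str
    polyline: tuple  # ((x, y), ...) with >= 1 point; a single point = stationary child
    school: str
    gender: str
    year_group: str
    activity: str
    play_type: str | None = None
    session: str = ""
    zone_observed: str = ""

    def __post_init__(self) -> None:
        if len(self.polyline) < 1:
            raise ValueError(f"trajectory {self.id}: empty polyline")
        arr = np.asarray(self.polyline, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(f"trajectory {self.id}: non-finite coordinates")
        if self.gender not in GENDERS:
            raise ValueError(f"trajectory {self.id}: unknown gender {self.gender!r}")
        if self.year_group not in YEAR_GROUPS:
            raise ValueError(f"trajectory {self.id}: unknown year_group {self.year_group!r}")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"trajectory {self.id}: unknown activity {self.activity!r}")
        if self.activity == "play" and not self.play_type:
            raise ValueError(f"trajectory {self.id}: activity 'play' requires a play_type")
        if self.activity != "play" and self.play_type:
            raise ValueError(
                f"trajectory {self.id}: play_type given for non-play activity"
            )

    @property
    def geometry(self):
        pts = [tuple(p) for p in self.polyline]
        uniq = [pts[0]]
        for p in pts[1:]:
            if p != uniq[-1]:
                uniq.append(p)
        return Point(uniq[0]) if len(uniq) == 1 else LineString(uniq)

    def group_key(self, group_by=("gender", "year_group")) -> str:
        return ":".join(str(getattr(self, a)) for a in group_by)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = (
    "id",
    "school",
    "gender",
    "year_group",
    "activity",
    "play_type",
    "session",
    "wkt",
)


def load_trajectories(path) -> list[TrajectoryRecord]:
    """Read trajectory records from a CSV with a WKT geometry column.

    Rows that violate the schema (unknown gender/year codes, empty
    geometry, play without play_type, ...) are rejected and logged with
    their line number; valid rows are returned.
    """
    df = pd.read_csv(str(path))
    missing = {"id", "gender", "year_group", "activity", "wkt"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks columns: {sorted(missing)}")
    records: list[TrajectoryRecord] = []
    n_rejected = 0
    for i, rec in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            geom = shapely_wkt.loads(rec["wkt"])
            if geom.is_empty:
                raise ValueError("empty geometry")
            if geom.geom_type == "Point":
                polyline = ((geom.x, geom.y),)
            elif geom.geom_type == "LineString":
                polyline = tuple((x, y) for x, y in geom.coords)
            else:
                raise ValueError(f"unsupported geometry {geom.geom_type}")
            play_type = rec.get("play_type")
            if isinstance(play_type, float) and np.isnan(play_type):
                play_type = None
            records.append(
                TrajectoryRecord(
                    id=str(rec["id"]),
                    polyline=polyline,
                    school=str(rec.get("school", "")),
                    gender=str(rec["gender"]),
                    year_group=str(rec["year_group"]),
                    activity=str(rec["activity"]),
                    play_type=play_type,
                    session=str(rec.get("session", "")),
                    zone_observed=str(rec.get("zone_observed", "")),
                )
            )
        except (ValueError, shapely.errors.ShapelyError) as exc:
            n_rejected += 1
            logger.warning("trajectory file line %d rejected: %s", line_no, exc)
    if n_rejected:
        logger.warning("rejected %d invalid trajectory rows", n_rejected)
    return records


def save_trajectories(records: list[TrajectoryRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "school": r.school,
                "gender": r.gender,
                "year_group": r.year_group,
                "activity": r.activity,
                "play_type": r.play_type,
                "session": r.session,
                "zone_observed": r.zone_observed,
                "wkt": r.geometry.wkt,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Buffering and rasterization
# ---------------------------------------------------------------------------

def buffer_trajectory(traj: TrajectoryRecord, radius: float = 0.70):
    """Round-capped, round-joined planar buffer of the trajectory.

    A stationary (single-point) record yields a disc of the given radius.
    """
    if radius <= 0:
        raise ValueError("buffer radius must be > 0")
    return traj.geometry.buffer(radius, quad_segs=BUFFER_QUAD_SEGS)


@dataclass
class HeatmapLayer:
    """Usage counts for one demographic group over the whole lattice."""

    group: str
    counts: np.ndarray  # int, length = lattice.n_cells
    n_trajectories: int


@dataclass
class RasterizeResult:
    layers: list[HeatmapLayer]
    counts: pd.DataFrame  # long-format cell x group regression input
    out_of_frame: int
    nonwalkable_touches: int

    def layer(self, group: str) -> HeatmapLayer:
        for l in self.layers:
            if l.group == group:
                return l
        raise KeyError(group)


def rasterize_counts(
    trajs: list[TrajectoryRecord],
    lattice: GridLattice,
    radius: float = 0.70,
    group_by: tuple = ("gender", "year_group"),
    vmd: VMDField | None = None,
) -> RasterizeResult:
    """Count, per cell and demographic group, the distinct trajectories
    whose buffer overlaps the cell with positive area.

    Returns per-group heatmap layers plus a pooled "all" layer, and a
    long-format (cell, group) table joined to zone (and VMD when a field
    is supplied) ready for the regression stage.  Trajectories whose
    buffer misses the lattice entirely are tallied as out-of-frame.
    """
    if radius <= 0:
        raise ValueError("buffer radius must be > 0")
    n_cells = lattice.n_cells
    cells = lattice.cell_polygons()
    tree = STRtree(cells)

    groups = sorted({t.group_key(group_by) for t in trajs})
    gindex = {g: i for i, g in enumerate(groups)}
    layer_counts = {g: np.zeros(n_cells, dtype=np.int64) for g in groups}
    all_counts = np.zeros(n_cells, dtype=np.int64)
    n_by_group = {g: 0 for g in groups}
    for t in trajs:
        n_by_group[t.group_key(group_by)] += 1

    # bulk geometry path: a cell touches a trajectory's buffer with
    # positive area iff the cell is within the buffer radius of the path;
    # pairs in the thin tangency ring (where buffer polygonisation and
    # the sliver threshold matter) are re-checked with the exact
    # buffer-intersection area
    ring_delta = min(1e-3, 0.5 * radius)
    paths = np.array([t.geometry for t in trajs], dtype=object)
    ti, ci = tree.query(paths, predicate="dwithin", distance=radius)
    if ti.size:
        sure = shapely.dwithin(paths[ti], cells[ci], radius - ring_delta)
        ring = np.flatnonzero(~sure)
        keep = sure.copy()
        if ring.size:
            buf_cache: dict[int, object] = {}
            for k in ring:
                t_id = int(ti[k])
                if t_id not in buf_cache:
                    buf_cache[t_id] = shapely.buffer(
                        paths[t_id], radius, quad_segs=BUFFER_QUAD_SEGS
                    )
                area = shapely.area(shapely.intersection(buf_cache[t_id], cells[ci[k]]))
                keep[k] = area > TOUCH_AREA_EPS
        ti, ci = ti[keep], ci[keep]
    tgroups = np.array([gindex[t.group_key(group_by)] for t in trajs])
    out_of_frame = int(len(trajs) - len(np.unique(ti)))
    np.add.at(all_counts, ci, 1)
    for g, gi in gindex.items():
        sel = tgroups[ti] == gi
        np.add.at(layer_counts[g], ci[sel], 1)

    nonwalkable_touches = int(all_counts[~lattice.walkable].sum())
    if nonwalkable_touches:
        logger.info(
            "%d cell-touches fall on non-walkable cells (buffer spill-over)",
            nonwalkable_touches,
        )

    layers = [
        HeatmapLayer(g, layer_counts[g], n_by_group[g]) for g in groups
    ] + [HeatmapLayer("all", all_counts, len(trajs))]

    counts_df = cell_group_table(layers[:-1], lattice, vmd)
    return RasterizeResult(layers, counts_df, out_of_frame, nonwalkable_touches)


def cell_group_table(
    layers: list[HeatmapLayer], lattice: GridLattice, vmd: VMDField | None = None
) -> pd.DataFrame:
    """Long-format (cell, group) count table over walkable cells.

    When a VMD field is given, rows are restricted to cells of the
    largest visibility component with a defined VMD (the regression
    population) and a ``vmd`` column is attached.
    """
    if vmd is not None:
        ok = np.isfinite(vmd.values) & vmd.in_largest_component()
        cell_idx = vmd.node_index[ok]
        vmd_vals = vmd.values[ok]
    else:
        cell_idx = lattice.walkable_indices()
        vmd_vals = np.full(len(cell_idx), np.nan)
    frames = []
    for layer in layers:
        frames.append(
            pd.DataFrame(
                {
                    "cell": cell_idx,
                    "zone": lattice.zone_of[cell_idx],
                    "vmd": vmd_vals,
                    "group": layer.group,
                    "count": layer.counts[cell_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def heatmap_frame(layers: list[HeatmapLayer], lattice: GridLattice) -> pd.DataFrame:
    """Long CSV schema (row, col, group, count) for all layers."""
    frames = []
    for layer in layers:
        frames.append(
            pd.DataFrame(
                {
                    "row": lattice.row,
                    "col": lattice.col,
                    "group": layer.group,
                    "count": layer.counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def export_heatmap(layers: list[HeatmapLayer], lattice: GridLattice, path) -> None:
    heatmap_frame(layers, lattice).to_csv(path, index=False)


def render_heatmap(layer: HeatmapLayer, lattice: GridLattice, png_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.zeros((lattice.nrows, lattice.ncols))
    img[lattice.row, lattice.col] = layer.counts
    fig, ax = plt.subplots(figsize=(8, 8 * lattice.nrows / max(lattice.ncols, 1)))
    m = ax.imshow(img, origin="lower", cmap="inferno", interpolation="nearest")
    fig.colorbar(m, ax=ax, label=f"usage count ({layer.group})")
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# Ball-game exclusion
# ---------------------------------------------------------------------------

def filter_ball_games(trajs: list[TrajectoryRecord]) -> list[TrajectoryRecord]:
    """Drop records whose play type is a ball game (idempotent).

    Ball games are institutionally allocated to designated fields, so a
    child playing one did not freely choose a location; excluding them
    isolates configurational preference from allocation.  Removal counts
    are logged per demographic group.
    """
    removed: dict[str, int] = {}
    kept = []
    for t in trajs:
        if t.play_type is not None and t.play_type.strip().lower() == BALL_GAME:
            g = t.group_key()
            removed[g] = removed.get(g, 0) + 1
        else:
            kept.append(t)
    if removed:
        logger.info(
            "excluded %d ball-game trajectories (%s)",
            sum(removed.values()),
            ", ".join(f"{g}: {n}" for g, n in sorted(removed.items())),
        )
    return kept
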