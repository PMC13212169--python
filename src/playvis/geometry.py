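"""Playground layout geometry and the analysis lattice.

A playground is represented by a boundary polygon, a set of visual
obstruction polygons (objects tall enough to block a child's line of
sight, i.e. reaching above eye level), and a set of named zones
(designated play areas such as a football pitch, plus whatever the
school treats as undesignated leftover space).

All coordinates are planar metres in a local projected frame; no
geographic CRS handling is performed.  The unit of analysis for every
downstream stage is a square lattice cell, 45 cm by default, matching
the footprint of a stationary child.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon, shape, mapping

logger = logging.getLogger("playvis")

#: Tolerance (metres) beyond which a zone polygon sticking out of the
#: boundary is clipped with a warning rather than accepted.
ZONE_TOLERANCE = 0.01

UNDESIGNATED = "undesignated"


class LayoutError(ValueError):
    """Raised for invalid playground layout input."""


@dataclass(frozen=True)
class Zone:
    name: str
    designated: bool
    polygon: Polygon


@dataclass
class PlaygroundLayout:
    """Boundary, eye-level obstructions and named zones of one playground.

    Obstruction polygons are assumed to be pre-filtered to objects that
    reach child eye level (1.2 m); the filter itself is a data-preparation
    step, not something this class re-checks.
    """

    boundary: Polygon
    obstructions: list[Polygon] = field(default_factory=list)
    zones: list[Zone] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.boundary, Polygon) or not self.boundary.is_valid:
            raise LayoutError("boundary must be a valid simple polygon")
        if self.boundary.area <= 0:
            raise LayoutError("boundary must have positive area")
        for i, obs in enumerate(self.obstructions):
            if not obs.is_valid:
                raise LayoutError(f"obstruction {i} is self-intersecting or invalid")
            bminx, bminy, bmaxx, bmaxy = self.boundary.bounds
            ominx, ominy, omaxx, omaxy = obs.bounds
            if omaxx < bminx or ominx > bmaxx or omaxy < bminy or ominy > bmaxy:
                raise LayoutError(
                    f"obstruction {i} does not intersect the boundary bounding box"
                )
        names = [z.name for z in self.zones]
        if len(names) != len(set(names)):
            raise LayoutError(f"zone names are not unique: {sorted(names)}")
        clipped = []
        for z in self.zones:
            if not z.polygon.is_valid:
                raise LayoutError(f"zone {z.name!r} polygon is invalid")
            outside = z.polygon.difference(self.boundary)
            if outside.area > 0:
                # hausdorff-style check: anything protruding more than the
                # tolerance is clipped back to the boundary
                if not z.polygon.within(self.boundary.buffer(ZONE_TOLERANCE)):
                    logger.warning(
                        "zone %r extends beyond the boundary; clipping to boundary",
                        z.name,
                    )
                inter = z.polygon.intersection(self.boundary)
                if inter.is_empty or inter.area <= 0:
                    raise LayoutError(f"zone {z.name!r} lies entirely outside the boundary")
                # keep the largest polygonal piece
                if inter.geom_type == "Polygon":
                    poly = inter
                else:
                    poly = max(
                        (g for g in inter.geoms if g.geom_type == "Polygon"),
                        key=lambda g: g.area,
                    )
                z = Zone(z.name, z.designated, poly)
            clipped.append(z)
        self.zones = clipped

    @property
    def zone_names(self) -> list[str]:
        return [z.name for z in self.zones]


@dataclass(frozen=True)
class GridSpec:
    """Parameters of the analysis lattice.

    cell_size : side of the square cell in metres (0.45 by default — the
        footprint of a static child).
    origin : (x, y) of the lattice origin; ``None`` places it at the min
        corner of the boundary's axis-aligned bounding box.
    buffer_radius : radius in metres of the buffer drawn around each
        movement trajectory (0.70 by default — the space a moving child
        takes up).
    eye_level : child eye level in metres used when the obstruction map
        was drawn; carried as metadata only.
    """

    cell_size: float = 0.45
    origin: tuple[float, float] | None = None
    buffer_radius: float = 0.70
    eye_level: float = 1.20

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.buffer_radius <= 0:
            raise ValueError("buffer_radius must be > 0")


@dataclass
class GridLattice:
    """Square-cell tessellation of a layout's bounding box.

    Cells are stored row-major in flat arrays; ``walkable`` marks cells
    whose centroid lies inside the boundary (closed) and strictly outside
    every obstruction; ``zone_of`` holds one zone name per cell
    ("undesignated" where no zone polygon covers the centroid).
    """

    spec: GridSpec
    origin: tuple[float, float]
    nrows: int
    ncols: int
    row: np.ndarray
    col: np.ndarray
    cx: np.ndarray
    cy: np.ndarray
    walkable: np.ndarray
    zone_of: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def n_walkable(self) -> int:
        return int(self.walkable.sum())

    def cell_polygons(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Shapely boxes for the given flat cell indices (all by default)."""
        if indices is None:
            indices = np.arange(self.n_cells)
        s = self.spec.cell_size
        x0 = self.origin[0] + self.col[indices] * s
        y0 = self.origin[1] + self.row[indices] * s
        return shapely.box(x0, y0, x0 + s, y0 + s)

    def walkable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.walkable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.row,
                "col": self.col,
                "cx": self.cx,
                "cy": self.cy,
                "walkable": self.walkable,
                "zone": self.zone_of,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Layout I/O
# ---------------------------------------------------------------------------

def _polygon_from_geojson(geom: dict, ident: str) -> Polygon:
    g = shape(geom)
    if g.geom_type != "Polygon":
        raise LayoutError(f"feature {ident}: expected Polygon, got {g.geom_type}")
    if not g.is_valid:
        raise LayoutError(f"feature {ident}: self-intersecting polygon")
    return g


def load_layout(path) -> PlaygroundLayout:
    """Read a playground layout from GeoJSON or a CSV with a WKT column.

    Every feature/row must carry a ``role`` attribute in
    ``{boundary, obstruction, zone}``; zone features additionally carry
    ``name`` and (optionally) ``designated``.  Exactly one boundary is
    required.
    """
    path = str(path)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            fc = json.load(fh)
        rows = []
        for i, feat in enumerate(fc.get("features", [])):
            props = feat.get("properties") or {}
            rows.append((str(i), props, shape(feat["geometry"])))
    else:
        df = pd.read_csv(path)
        if "wkt" not in df.columns or "role" not in df.columns:
            raise LayoutError("layout CSV needs 'role' and 'wkt' columns")
        rows = []
        for i, rec in df.iterrows():
            rows.append((str(i), rec.to_dict(), shapely_wkt.loads(rec["wkt"])))

    boundary_feats, obstructions, zones = [], [], []
    for ident, props, geom in rows:
        role = props.get("role")
        if geom.geom_type != "Polygon":
            raise LayoutError(f"feature {ident}: expected Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise LayoutError(f"feature {ident}: self-intersecting polygon")
        if role == "boundary":
            boundary_feats.append((ident, geom))
        elif role == "obstruction":
            obstructions.append(geom)
        elif role == "zone":
            name = props.get("name")
            if not name or (isinstance(name, float) and math.isnan(name)):
                raise LayoutError(f"feature {ident}: zone without a name")
            designated = bool(props.get("designated", True))
            zones.append(Zone(str(name), designated, geom))
        else:
            raise LayoutError(f"feature {ident}: unknown role {role!r}")

    if len(boundary_feats) == 0:
        raise LayoutError("no boundary feature in layout")
    if len(boundary_feats) > 1:
        idents = ", ".join(i for i, _ in boundary_feats)
        raise LayoutError(f"multiple boundary features (ids {idents}); exactly one required")

    return PlaygroundLayout(boundary_feats[0][1], obstructions, zones)


def save_layout(layout: PlaygroundLayout, path) -> None:
    """Write a layout as a GeoJSON feature collection (role/name/designated)."""
    feats = [
        {
            "type": "Feature",
            "properties": {"role": "boundary"},
            "geometry": mapping(layout.boundary),
        }
    ]
    for obs in layout.obstructions:
        feats.append(
            {"type": "Feature", "properties": {"role": "obstruction"}, "geometry": mapping(obs)}
        )
    for z in layout.zones:
        feats.append(
            {
                "type": "Feature",
                "properties": {"role": "zone", "name": z.name, "designated": z.designated},
                "geometry": mapping(z.polygon),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Lattice construction
# ---------------------------------------------------------------------------

def build_grid(layout: PlaygroundLayout, spec: GridSpec | None = None) -> GridLattice:
    """Tile the boundary's bounding box with square cells and classify them.

    A cell is walkable when its centroid lies inside the (closed) boundary
    and strictly outside every obstruction's interior.  Zone labels are
    assigned by :func:`assign_zones`.
    """
    if spec is None:
        spec = GridSpec()
    minx, miny, maxx, maxy = layout.boundary.bounds
    width, height = maxx - minx, maxy - miny
    s = spec.cell_size
    if s > width and s > height:
        raise LayoutError(
            f"cell_size {s} exceeds the boundary extent ({width:.3g} x {height:.3g} m)"
        )
    origin = spec.origin if spec.origin is not None else (minx, miny)
    ncols = max(1, math.ceil((maxx - origin[0]) / s - 1e-9))
    nrows = max(1, math.ceil((maxy - origin[1]) / s - 1e-9))

    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    row = rr.ravel()
    col = cc.ravel()
    cx = origin[0] + (col + 0.5) * s
    cy = origin[1] + (row + 0.5) * s

    centroids = shapely.points(np.column_stack([cx, cy]))
    walkable = shapely.covers(layout.boundary, centroids)
    for obs in layout.obstructions:
        walkable &= ~shapely.contains_properly(obs, centroids)

    lat = GridLattice(
        spec=spec,
        origin=(float(origin[0]), float(origin[1])),
        nrows=nrows,
        ncols=ncols,
        row=row,
        col=col,
        cx=cx,
        cy=cy,
        walkable=walkable,
        zone_of=np.full(nrows * ncols, UNDESIGNATED, dtype=object),
    )
    return assign_zones(lat, layout)


def assign_zones(lattice: GridLattice, layout: PlaygroundLayout) -> GridLattice:
    """Label each cell with the zone covering its centroid.

    Zone polygons are treated as closed (a centroid exactly on the edge is
    inside).  Where zones overlap, the first-declared zone wins and a
    warning is emitted.  Cells covered by no zone are "undesignated".
    """
    centroids = shapely.points(np.column_stack([lattice.cx, lattice.cy]))
    labels = np.full(lattice.n_cells, UNDESIGNATED, dtype=object)
    claimed = np.zeros(lattice.n_cells, dtype=bool)
    overlap_warned = False
    for z in layout.zones:
        inside = shapely.covers(z.polygon, centroids)
        if not overlap_warned and bool((inside & claimed).any()):
            logger.warning(
                "overlapping zones; declaration order resolves the conflict "
                "(first zone keeps the cell)"
            )
            overlap_warned = True
        take = inside & ~claimed
        labels[take] = z.name
        claimed |= inside
    lattice.zone_of = labels
    return lattice
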