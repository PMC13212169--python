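"""Synthetic playgrounds, usage intensities and trajectories.

No public playground-observation dataset exists at the cell level, so
this module generates data with the statistical structure the analysis
assumes, making every pipeline stage testable end to end:

* layouts on four templates — a featureless ``convex`` court; an
  ``integrated-fields`` playground with ball-game fields placed centrally
  inside the main space; a ``separated-fields`` playground whose ball
  fields sit behind a blocking structure at the back; and seeded
  ``random-obstacles`` layouts for property tests;
* direct per-cell NB2 counts from the generating model
  log mu = beta0 + gamma_g + beta_g * VMD + u_zone, u_zone ~ N(0, sigma^2)
  — the clean path for parameter-recovery tests;
* trajectory synthesis — bounded random walks started proportionally to
  the group's intensity surface, with a configurable share of ball-game
  trajectories confined to designated ball zones — the noisy path for
  end-to-end integration tests (rasterisation distorts the clean model
  by design).

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.prepared import prep

from .geometry import PlaygroundLayout, Zone, GridSpec, GridLattice, build_grid
from .visibility import VMDField, build_visibility_graph, compute_vmd
from .heatmap import TrajectoryRecord

logger = logging.getLogger("playvis")

TEMPLATES = ("convex", "integrated-fields", "separated-fields", "random-obstacles")


@dataclass(frozen=True)
class GroupParams:
    """Generating parameters for one gender x year-group cell.

    ``gamma`` is the baseline log-count offset, ``slope`` the VMD
    coefficient of the group's free (non-ball-game) movement, and
    ``ball_share`` the fraction of the group's trajectories that are
    ball games (confined to designated ball zones rather than following
    the visual-depth preference).
    """

    gender: str
    year_group: str
    gamma: float
    slope: float
    ball_share: float = 0.0

    @property
    def key(self) -> str:
        return f"{self.gender}:{self.year_group}"


# Default slopes span the percent-change magnitudes reported for real
# playgrounds (about -50% .. +50% per VMD unit): exp(-0.6)-1 = -45%,
# exp(0.4)-1 = +49%.  Ball-game shares reflect the strong male skew of
# ball games in observational studies.
DEFAULT_GROUPS = (
    GroupParams("male", "Y3/4", gamma=0.00, slope=-0.3, ball_share=0.45),
    GroupParams("female", "Y3/4", gamma=-0.05, slope=0.4, ball_share=0.06),
    GroupParams("male", "Y5/6", gamma=0.05, slope=-0.6, ball_share=0.55),
    GroupParams("female", "Y5/6", gamma=-0.10, slope=-0.2, ball_share=0.04),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for the synthetic generator.

    The defaults emulate the observational structure of a two-school
    breaktime campaign: a 1,400-1,600 m^2 playground, a 45 cm analysis
    grid, a 70 cm trajectory buffer, roughly 1,450 ten-second
    trajectories balanced over four gender x year strata, and NB2 counts
    that are log-linear in VMD with zone-level intercepts.
    """

    template: str = "integrated-fields"
    boundary_size: tuple[float, float] | None = None  # (width, height) metres
    cell_size: float = 0.45
    buffer_radius: float = 0.70
    beta0: float = 1.3
    groups: tuple[GroupParams, ...] = DEFAULT_GROUPS
    sigma_zone: float = 0.5
    theta: float = 1.5
    n_trajectories_per_group: int = 360
    mean_path_length: float = 8.0  # metres covered in 10 s
    step_length: float = 0.5
    turn_sd: float = 1.0  # radians
    tether_radius: float = 1.2  # metres a playing child roams from their spot
    ball_zone_names: tuple[str, ...] | None = None  # template default when None
    n_random_obstacles: int = 6
    n_random_zones: int = 5
    max_step_retries: int = 8

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.sigma_zone < 0:
            raise ValueError("sigma_zone must be >= 0")
        if self.n_trajectories_per_group < 0:
            raise ValueError("n_trajectories_per_group must be >= 0")
        for g in self.groups:
            if not 0.0 <= g.ball_share <= 1.0:
                raise ValueError("ball_share must be in [0, 1]")

    def group_map(self) -> dict[str, GroupParams]:
        return {g.key: g for g in self.groups}

    def ball_zones(self) -> tuple[str, ...]:
        if self.ball_zone_names is not None:
            return self.ball_zone_names
        return {
            "convex": (),
            "integrated-fields": ("football", "basketball", "hockey", "tennis"),
            "separated-fields": ("kingball", "football", "basketball"),
            "random-obstacles": (),
        }[self.template]


def ball_game_contrast_config(**overrides) -> GeneratorConfig:
    """Scenario emulating the ball-game exclusion contrast.

    Boys' free movement prefers visually deep space (positive slopes)
    while most of their trajectories are ball games confined to the
    central, visually shallow fields — so the slope fitted on all data
    is negative for boys and flips sign once ball games are excluded.
    """
    groups = (
        GroupParams("male", "Y3/4", gamma=0.00, slope=1.0, ball_share=0.75),
        GroupParams("female", "Y3/4", gamma=-0.05, slope=-0.02, ball_share=0.05),
        GroupParams("male", "Y5/6", gamma=0.05, slope=0.55, ball_share=0.70),
        GroupParams("female", "Y5/6", gamma=-0.10, slope=-0.55, ball_share=0.04),
    )
    return GeneratorConfig(template="integrated-fields", groups=groups, **overrides)


# ---------------------------------------------------------------------------
# Layout templates
# ---------------------------------------------------------------------------

def _scaled_boxes(w, h, items):
    """Boxes given in unit coordinates of a 47 x 30 reference frame."""
    sx, sy = w / 47.0, h / 30.0
    return {
        name: box(x0 * sx, y0 * sy, x1 * sx, y1 * sy)
        for name, (x0, y0, x1, y1) in items.items()
    }


def generate_layout(config: GeneratorConfig, seed: int = 0) -> PlaygroundLayout:
    """Build a playground layout for the configured template.

    Named templates are deterministic in their geometry; the
    ``random-obstacles`` template draws obstruction and zone rectangles
    from the seeded generator.  Boundary defaults to ~1,400-1,600 m^2.
    """
    rng = np.random.default_rng(seed)
    t = config.template
    if t == "convex":
        w, h = config.boundary_size or (40.0, 36.0)
        return PlaygroundLayout(box(0, 0, w, h), [], [])

    if t == "integrated-fields":
        w, h = config.boundary_size or (47.0, 30.0)
        zones = _scaled_boxes(
            w,
            h,
            {
                "football": (14, 8, 26, 22),
                "basketball": (2, 20, 10, 28),
                "hockey": (28, 10, 38, 20),
                "tennis": (38, 2, 46, 12),
                "climbing frame": (2, 2, 10, 8),
            },
        )
        obstructions = list(
            _scaled_boxes(
                w,
                h,
                {
                    "shed": (0.5, 12, 3.5, 18),
                    "planter": (20, 0.5, 34, 2.0),
                    "storage": (41, 24, 46.5, 29),
                    "wall": (12, 24.5, 13, 29.5),
                    "hedge": (10, 3.5, 11, 7.5),
                    "planter2": (36, 13, 37.2, 21),
                    "canopy post": (5, 27, 9, 28.2),
                    "pocket wall": (40, 12.5, 46.5, 13.5),
                    "alcove wall": (0.5, 20.5, 1.8, 26.5),
                },
            ).values()
        )
        zlist = [Zone(n, True, p) for n, p in zones.items()]
        return PlaygroundLayout(box(0, 0, w, h), obstructions, zlist)

    if t == "separated-fields":
        w, h = config.boundary_size or (50.0, 32.0)
        sx, sy = w / 50.0, h / 32.0

        def b(x0, y0, x1, y1):
            return box(x0 * sx, y0 * sy, x1 * sx, y1 * sy)

        # a building wing walls off the back strip that hosts the ball
        # fields; the only way round (and the only sight line) is the
        # narrow corridor on the right.  Further walls, hedges and sheds
        # carve the main ground into partial rooms, giving the layout a
        # visual-depth profile comparable to real separated-field schools
        obstructions = [
            b(0, 22, 42, 24),  # blocking structure
            b(46, 22, 48.5, 26),  # planter narrowing the corridor mouth
            b(8, 26, 30, 27),  # divider inside the back strip
            b(4, 14.5, 6, 16.5),  # treehouse trunk
            b(24, 6, 26, 8),  # kiosk
            b(10, 12, 12, 20),  # hedge wall around the lower playground
            b(30, 14, 36, 15.5),  # storage row
            b(14, 0, 15, 8),  # L-walled court (south)
            b(15, 7, 24, 8),
            b(30, 2, 31, 10),  # fence
            b(20, 14, 21.5, 21),  # hedge
            b(38, 11, 46, 12),  # bench-and-planter row
            b(33, 16, 34, 21),  # planter
            b(2, 8, 8, 9),  # hedge
        ]
        zones = [
            Zone("football", True, b(1, 25, 22, 31)),
            Zone("basketball", True, b(24, 25, 35, 31)),
            Zone("kingball", True, b(38, 4, 45, 10)),
            Zone("climbing frame", True, b(8, 2, 18, 10)),
            Zone("treehouse", True, b(2, 12, 8, 19)),
            Zone("silent zone", True, b(40, 14, 48, 20)),
            Zone("lower playground", True, b(12, 14, 22, 20)),
        ]
        return PlaygroundLayout(box(0, 0, w, h), obstructions, zones)

    # random-obstacles: a mix of compact blocks (sheds, planters) and
    # thin wall-like blockers (hedges, fences), which is what gives real
    # playgrounds their visual-depth variation
    w, h = config.boundary_size or (40.0, 36.0)
    obstructions = []
    for i in range(config.n_random_obstacles):
        if i % 2 == 0:
            ow = rng.uniform(1.5, 5.0)
            oh = rng.uniform(1.5, 5.0)
        else:
            ow = rng.uniform(0.3, 0.6)
            oh = rng.uniform(0.35 * min(w, h), 0.6 * min(w, h))
            if rng.uniform() < 0.5:
                ow, oh = oh, ow
        x0 = rng.uniform(0.5, w - ow - 0.5)
        y0 = rng.uniform(0.5, h - oh - 0.5)
        obstructions.append(box(x0, y0, x0 + ow, y0 + oh))
    zones = []
    if config.n_random_zones > 0:
        # tile the boundary into a coarse grid and pick cells as zones so
        # zone polygons never overlap
        gx, gy = 3, max(2, int(np.ceil(config.n_random_zones / 3)) + 1)
        cells = [(i, j) for i in range(gx) for j in range(gy)]
        pick = rng.choice(len(cells), size=min(config.n_random_zones, len(cells)), replace=False)
        for k, ci in enumerate(pick):
            i, j = cells[ci]
            x0, x1 = i * w / gx, (i + 1) * w / gx
            y0, y1 = j * h / gy, (j + 1) * h / gy
            mx, my = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
            zones.append(Zone(f"zone{k + 1}", True, box(x0 + mx, y0 + my, x1 - mx, y1 - my)))
    return PlaygroundLayout(box(0, 0, w, h), obstructions, zones)


# ---------------------------------------------------------------------------
# Direct cell-count path
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Exact generating values: parameters, zone intercepts, per-cell
    intensities per group, and the seed used."""

    seed: int
    beta0: float
    sigma_zone: float
    theta: float
    group_params: dict  # key -> {"gamma":, "slope":, "ball_share":}
    u_zone: dict  # zone name -> drawn random intercept
    cell_index: np.ndarray  # flat lattice indices of modelled cells
    vmd: np.ndarray
    zone: np.ndarray
    intensities: dict  # group key -> per-cell mu (aligned with cell_index)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "beta0": self.beta0,
            "sigma_zone": self.sigma_zone,
            "theta": self.theta,
            "group_params": self.group_params,
            "u_zone": self.u_zone,
            "cell_index": self.cell_index.tolist(),
            "vmd": self.vmd.tolist(),
            "zone": list(map(str, self.zone)),
            "intensities": {k: v.tolist() for k, v in self.intensities.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def generate_cell_counts(
    layout: PlaygroundLayout,
    lattice: GridLattice,
    vmd: VMDField,
    config: GeneratorConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw NB2 counts per (walkable cell, group) from the generating model.

    mu = exp(beta0 + gamma_g + slope_g * VMD_c + u_zone(c)), with one
    N(0, sigma^2) intercept per zone and NB2 sampling via the
    gamma-Poisson mixture.  Cells outside the largest visibility
    component (no defined VMD) are excluded, mirroring the regression
    population.
    """
    rng = np.random.default_rng(seed)
    ok = np.isfinite(vmd.values) & vmd.in_largest_component()
    cell_idx = vmd.node_index[ok]
    v = vmd.values[ok]
    zone = lattice.zone_of[cell_idx]
    zone_names = sorted(set(zone))
    u = {z: (rng.normal(0.0, config.sigma_zone) if config.sigma_zone > 0 else 0.0) for z in zone_names}
    u_cell = np.array([u[z] for z in zone])

    frames = []
    intensities = {}
    for g in config.groups:
        mu = np.exp(config.beta0 + g.gamma + g.slope * v + u_cell)
        lam = rng.gamma(shape=config.theta, scale=mu / config.theta)
        counts = rng.poisson(lam)
        intensities[g.key] = mu
        frames.append(
            pd.DataFrame(
                {
                    "cell": cell_idx,
                    "zone": zone,
                    "vmd": v,
                    "group": g.key,
                    "count": counts,
                }
            )
        )
    truth = SyntheticTruth(
        seed=seed,
        beta0=config.beta0,
        sigma_zone=config.sigma_zone,
        theta=config.theta,
        group_params={
            g.key: {"gamma": g.gamma, "slope": g.slope, "ball_share": g.ball_share}
            for g in config.groups
        },
        u_zone={z: float(val) for z, val in u.items()},
        cell_index=cell_idx,
        vmd=v,
        zone=zone,
        intensities=intensities,
    )
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# Trajectory path
# ---------------------------------------------------------------------------

_PLAY_TYPES = ("chasing", "skipping", "climbing", "imaginative play")


def _random_walk(rng, start, n_steps, step_len, turn_sd, inside, retries, anchor=None, tether=None):
    """Bounded random walk; returns a list of points (>= 1).

    ``inside`` is a predicate for admissible points.  When ``anchor`` and
    ``tether`` are given the walk is tethered: steps may not leave the
    tether radius around the anchor, emulating a child playing around a
    chosen spot rather than commuting across the playground.  Steps that
    cannot be placed after the retry budget are skipped (the child
    lingers in place).
    """
    pts = [start]
    angle = rng.uniform(0, 2 * np.pi)
    x, y = start
    for _ in range(n_steps):
        placed = False
        a = angle
        for _ in range(retries):
            a = angle + rng.normal(0.0, turn_sd)
            nx_, ny_ = x + step_len * np.cos(a), y + step_len * np.sin(a)
            if anchor is not None and (nx_ - anchor[0]) ** 2 + (ny_ - anchor[1]) ** 2 > tether**2:
                angle = rng.uniform(0, 2 * np.pi)
                continue
            if inside(nx_, ny_):
                placed = True
                break
            angle = rng.uniform(0, 2 * np.pi)  # stuck: reorient
        if not placed:
            continue
        x, y, angle = nx_, ny_, a
        pts.append((x, y))
    return pts


def generate_trajectories(
    layout: PlaygroundLayout,
    lattice: GridLattice,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    seed: int = 0,
) -> list[TrajectoryRecord]:
    """Synthesise 10-second trajectory records for every group.

    Free-play trajectories are tethered walks around an anchor spot
    drawn with probability proportional to the group's true intensity,
    divided by the local reach-kernel mass (the number of modelled cells
    a trajectory anchored there can touch) so that realised per-cell
    touch rates follow the generating log-linear model rather than the
    geometry of open space.  Ball-game trajectories (a per-group share)
    start uniformly in the designated ball zones and roam inside them,
    emulating institutional allocation.
    """
    rng = np.random.default_rng(seed)
    walk = prep(
        layout.boundary.difference(shapely.unary_union(layout.obstructions))
        if layout.obstructions
        else layout.boundary
    )
    ball_names = set(config.ball_zones())
    ball_polys = [z.polygon for z in layout.zones if z.name in ball_names]
    ball_union = shapely.unary_union(ball_polys) if ball_polys else None
    ball_prep = prep(ball_union) if ball_union is not None else None

    cell_idx = truth.cell_index
    zone = truth.zone
    is_ball_cell = np.isin(zone, list(ball_names))
    cx = lattice.cx[cell_idx]
    cy = lattice.cy[cell_idx]
    half = lattice.spec.cell_size / 2

    def inside_free(x, y):
        return walk.contains(shapely.Point(x, y))

    def inside_ball(x, y):
        return ball_prep.contains(shapely.Point(x, y))

    # reach-kernel mass: how many modelled cells a trajectory anchored at
    # each cell can touch (tether + buffer radius); anchor probabilities
    # are deflated by it so touch rates track the target intensities
    from scipy.spatial import cKDTree

    pts_cells = np.column_stack([lattice.cx[cell_idx], lattice.cy[cell_idx]])
    tree = cKDTree(pts_cells)
    reach = config.tether_radius + config.buffer_radius
    kernel_mass = np.array([len(ix) for ix in tree.query_ball_point(pts_cells, reach)])

    records = []
    tid = 0
    for g in config.groups:
        n = config.n_trajectories_per_group
        if n == 0:
            continue
        mu = truth.intensities[g.key]
        w_free = mu / kernel_mass
        p_free = w_free / w_free.sum()
        n_ball = rng.binomial(n, g.ball_share) if g.ball_share > 0 else 0
        if n_ball > 0 and ball_union is None:
            logger.warning("ball_share > 0 but layout has no ball zones; treating as free play")
            n_ball = 0
        for j in range(n):
            is_ball = j < n_ball
            if is_ball:
                cand = np.flatnonzero(is_ball_cell)
                k = rng.choice(cand)
                inside = inside_ball
            else:
                k = rng.choice(len(cell_idx), p=p_free)
                inside = inside_free
            # jitter the start within the cell, rejecting inadmissible spots
            for _ in range(config.max_step_retries):
                sx = cx[k] + rng.uniform(-half, half)
                sy = cy[k] + rng.uniform(-half, half)
                if inside(sx, sy):
                    break
            else:
                sx, sy = cx[k], cy[k]
                if not inside(sx, sy):
                    continue  # pathological cell; skip trajectory
            length = max(0.0, rng.gamma(4.0, config.mean_path_length / 4.0))
            n_steps = int(round(length / config.step_length))
            pts = _random_walk(
                rng,
                (sx, sy),
                n_steps,
                config.step_length,
                config.turn_sd,
                inside,
                config.max_step_retries,
                anchor=None if is_ball else (sx, sy),
                tether=None if is_ball else config.tether_radius,
            )
            tid += 1
            if is_ball:
                activity, play_type = "play", "ball game"
            else:
                u01 = rng.uniform()
                if u01 < 0.80:
                    activity, play_type = "play", _PLAY_TYPES[rng.integers(len(_PLAY_TYPES))]
                elif u01 < 0.95:
                    activity, play_type = "conversation", None
                else:
                    activity, play_type = "other", None
            records.append(
                TrajectoryRecord(
                    id=f"t{tid:05d}",
                    polyline=tuple((float(px), float(py)) for px, py in pts),
                    school=config.template,
                    gender=g.gender,
                    year_group=g.year_group,
                    activity=activity,
                    play_type=play_type,
                    session="s1",
                    zone_observed=str(zone[k]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Convenience pipelines
# ---------------------------------------------------------------------------

@dataclass
class SimulatedScene:
    """Layout, lattice and VMD field for one synthetic playground."""

    config: GeneratorConfig
    layout: PlaygroundLayout
    lattice: GridLattice
    vmd: VMDField


def simulate_scene(config: GeneratorConfig, seed: int = 0) -> SimulatedScene:
    """Layout -> lattice -> visibility graph -> VMD, in one call."""
    layout = generate_layout(config, seed)
    lattice = build_grid(layout, GridSpec(cell_size=config.cell_size, buffer_radius=config.buffer_radius))
    graph = build_visibility_graph(lattice, layout)
    vmd = compute_vmd(graph)
    return SimulatedScene(config, layout, lattice, vmd)


def simulate_counts(config: GeneratorConfig, seed: int = 0, scene: SimulatedScene | None = None):
    """Direct-path dataset: (scene, counts table, truth)."""
    if scene is None:
        scene = simulate_scene(config, seed)
    counts, truth = generate_cell_counts(scene.layout, scene.lattice, scene.vmd, config, seed)
    return scene, counts, truth


def simulate_trajectories(config: GeneratorConfig, seed: int = 0, scene: SimulatedScene | None = None):
    """Trajectory-path dataset: (scene, records, truth)."""
    if scene is None:
        scene = simulate_scene(config, seed)
    _, truth = generate_cell_counts(scene.layout, scene.lattice, scene.vmd, config, seed)
    records = generate_trajectories(scene.layout, scene.lattice, truth, config, seed)
    return scene, records, truth
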