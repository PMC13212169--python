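import numpy as np
import pytest
from shapely.geometry import box

import playvis as pv
from playvis.geometry import PlaygroundLayout, Zone, GridSpec, build_grid
from playvis.heatmap import TrajectoryRecord
from playvis.synthetic_data import (
    GeneratorConfig,
    GroupParams,
    generate_cell_counts,
    simulate_scene,
)
from playvis.visibility import build_visibility_graph, compute_vmd


@pytest.fixture(scope="session")
def closure_config():
    """Study-style scenario for end-to-end pipeline closure: the deep
    separated-fields layout, default effect sizes, no ball games, and a
    trajectory count high enough to test method closure rather than
    single-school power."""
    groups = tuple(
        GroupParams(g.gender, g.year_group, g.gamma, g.slope, 0.0)
        for g in pv.DEFAULT_GROUPS
    )
    return GeneratorConfig(
        template="separated-fields", groups=groups, n_trajectories_per_group=1600
    )


@pytest.fixture(scope="session")
def closure_scene(closure_config):
    return simulate_scene(closure_config, seed=0)


@pytest.fixture(scope="session")
def closure_truth(closure_config, closure_scene):
    """School-fixed generating truth: zone baselines are attributes of the
    (synthetic) school, so replicates resample observation sampling only."""
    sc = closure_scene
    _, truth = generate_cell_counts(sc.layout, sc.lattice, sc.vmd, closure_config, seed=0)
    return truth


@pytest.fixture(scope="session")
def rect_layout():
    """9 m x 4.5 m obstruction-free rectangle: tiles exactly into 20 x 10 cells."""
    return PlaygroundLayout(box(0, 0, 9, 4.5), [], [])


@pytest.fixture(scope="session")
def rect_lattice(rect_layout):
    return build_grid(rect_layout, GridSpec())


def make_record(
    id="t1",
    polyline=((1.0, 1.0),),
    gender="male",
    year_group="Y3/4",
    activity="play",
    play_type="chasing",
    **kw,
):
    return TrajectoryRecord(
        id=id,
        polyline=polyline,
        school="test",
        gender=gender,
        year_group=year_group,
        activity=activity,
        play_type=play_type,
        **kw,
    )


def random_obstacle_layout(rng, width=6.0, height=6.0, n_obstacles=2):
    """Small random layout for property tests; obstructions never touch the rim."""
    obstructions = []
    for _ in range(n_obstacles):
        ow, oh = rng.uniform(0.6, 2.0, 2)
        x0 = rng.uniform(0.3, width - ow - 0.3)
        y0 = rng.uniform(0.3, height - oh - 0.3)
        obstructions.append(box(x0, y0, x0 + ow, y0 + oh))
    return PlaygroundLayout(box(0, 0, width, height), obstructions, [])


def vmd_of(layout, cell_size=0.45):
    lattice = build_grid(layout, GridSpec(cell_size=cell_size))
    graph = build_visibility_graph(lattice, layout)
    return lattice, graph, compute_vmd(graph)
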