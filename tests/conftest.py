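import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from ctpffr.bc import HemodynamicState
from ctpffr.perfusion import MBFMap
from ctpffr.tree import CoronaryTree, Node, Segment, Stenosis


@pytest.fixture
def hemo():
    return HemodynamicState(sbp=120.0, dbp=80.0)  # MAP = 96


@pytest.fixture
def single_edge_tree():
    """One straight 10 mm segment of radius 2 mm, single outlet."""
    nodes = {0: Node(0, [0, 0, 0], 2.0), 1: Node(1, [10, 0, 0], 2.0)}
    segs = [Segment(0, 0, 1, 10.0, 2.0, 2.0)]
    return CoronaryTree(nodes, segs, [], {1: "LAD"}, 0)


@pytest.fixture
def stenosed_tube():
    """40 mm tube with a 60% focal stenosis in the middle."""
    nodes = {0: Node(0, [0, 0, 0], 2.0), 1: Node(1, [40, 0, 0], 2.0)}
    segs = [Segment(0, 0, 1, 40.0, 2.0, 2.0)]
    stens = [Stenosis(0, 0, 15.0, 10.0, 60.0)]
    return CoronaryTree(nodes, segs, stens, {1: "LAD"}, 0)


@pytest.fixture
def symmetric_bifurcation():
    r_child = 2.0 / 2.0 ** (1.0 / 3.0)  # Murray: 2 equal children of a r=2 parent
    nodes = {0: Node(0, [0, 0, 0], 2.0), 1: Node(1, [10, 0, 0], 2.0),
             2: Node(2, [20, 8, 0], r_child), 3: Node(3, [20, -8, 0], r_child)}
    segs = [Segment(0, 0, 1, 10.0, 2.0, 2.0),
            Segment(1, 1, 2, 13.0, r_child, r_child),
            Segment(2, 1, 3, 13.0, r_child, r_child)]
    return CoronaryTree(nodes, segs, [], {2: "LAD", 3: "LCX"}, 0)


@pytest.fixture
def uniform_map():
    """16^3 grid, all-true mask, constant MBF of 1.5 mL/min/mL."""
    shape = (16, 16, 16)
    return MBFMap(np.full(shape, 1.5), np.ones(shape, dtype=bool),
                  (0.625, 0.625, 1.25), (0.0, 0.0, 0.0))


def random_map_and_tree(n_side=20, n_outlets=5, seed=0):
    """Random map plus a degenerate star tree with the requested outlets."""
    rng = np.random.default_rng(seed)
    shape = (n_side, n_side, n_side)
    values = rng.uniform(0.0, 3.0, shape)
    mask = rng.random(shape) < 0.5
    mask.flat[0] = True  # never empty
    m = MBFMap(values, mask, (0.625, 0.625, 1.25), (0.0, 0.0, 0.0))
    extent = np.array(shape) * np.array(m.spacing)
    seeds = rng.uniform(0.0, 1.0, (n_outlets, 3)) * extent
    nodes = {0: Node(0, extent / 2.0 + [0, 0, extent[2]], 2.5)}
    segs, outlets = [], {}
    for i in range(n_outlets):
        nodes[i + 1] = Node(i + 1, seeds[i], 1.0)
        length = max(np.linalg.norm(seeds[i] - nodes[0].position), 1.0)
        segs.append(Segment(i, 0, i + 1, float(length), 1.0, 1.0))
        outlets[i + 1] = "LAD" if i % 2 == 0 else "LCX"
    return m, CoronaryTree(nodes, segs, [], outlets, 0)
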