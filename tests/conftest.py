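import numpy as np
import pytest

from spindlesim import CellGeometry, ParameterSet


@pytest.fixture
def geom():
    return CellGeometry(a=15.0)


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent scalar oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def oracle_inside(p, g):
    x, y, z = p
    return (x / g.a) ** 2 + (y / (0.9 * g.a)) ** 2 + (z / (0.7 * g.a)) ** 2 < 1.0


def oracle_ray_length(origin, direction, g, tol=1e-10):
    """Bisection on the containment predicate along the ray."""
    origin = np.asarray(origin, float)
    direction = np.asarray(direction, float)
    hi = 1.0
    while oracle_inside(origin + hi * direction, g):
        hi *= 2.0
        assert hi < 1e6
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if oracle_inside(origin + mid * direction, g):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_segment_distance(start, direction, length, point, n=4001):
    """Dense sampling of the segment."""
    t = np.linspace(0.0, length, n)
    pts = np.asarray(start)[None, :] + t[:, None] * np.asarray(direction)[None, :]
    return np.linalg.norm(pts - np.asarray(point)[None, :], axis=1).min()


def oracle_arm_crossing(start, direction, length, ch_pos, r_c):
    """Disk crossing via explicit plane intersection."""
    start = np.asarray(start, float)
    direction = np.asarray(direction, float)
    ch_pos = np.asarray(ch_pos, float)
    if direction[0] == 0.0:
        return False
    t = (ch_pos[0] - start[0]) / direction[0]
    if not (0.0 < t <= length):
        return False
    hit = start + t * direction
    return float(np.hypot(hit[1] - ch_pos[1], hit[2] - ch_pos[2])) <= r_c


@pytest.fixture
def oracles():
    return {
        "inside": oracle_inside,
        "ray_length": oracle_ray_length,
        "segment_distance": oracle_segment_distance,
        "arm_crossing": oracle_arm_crossing,
    }
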