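"""Cell geometry and the geometric predicates coupling MTs to chromosomes.

The cell cortex is a hard ellipsoidal envelope with semi-axes ``(a, 0.9a,
0.7a)`` along ``(x, y, z)`` and the origin at the cell centre.  The two
spindle poles sit at ``(-a/2, 0, 0)`` and ``(+a/2, 0, 0)`` and are fixed for
the whole run.  Microtubules are straight rays from a pole; a chromosome is a
point ``r`` carrying an arm disk of radius ``r_c`` (normal along x, the
pole--pole axis) and a kinetochore interaction sphere of radius ``r_k``.

Every predicate is provided in two forms: a scalar form operating on a single
MT (used by tests and as the brute-force oracle) and a vectorised form
operating on the array state (used by the simulation loop).  The vectorised
forms are exact, not approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEFT, RIGHT, NONE = -1, 1, 0  # tip-contact side codes (hemisphere facing pole 0/1)


@dataclass(frozen=True)
class CellGeometry:
    """Ellipsoidal cortex with fixed spindle poles.

    ``a`` is the *semi*-axis along x; with a full axis the poles at ``+-a/2``
    would lie on the cortex rather than strictly inside it.
    """

    a: float = 15.0

    @property
    def b(self) -> float:
        return 0.9 * self.a

    @property
    def c(self) -> float:
        return 0.7 * self.a

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def poles(self) -> np.ndarray:
        """Pole positions, shape (2, 3); pole 0 at -x, pole 1 at +x."""
        return np.array([[-self.a / 2.0, 0.0, 0.0], [self.a / 2.0, 0.0, 0.0]])

    @property
    def r_nucleus(self) -> float:
        """Radius of the sphere in which chromosomes are initially placed."""
        return 0.65 * self.a

    @property
    def r_cenpe_shell(self) -> float:
        """Radius of the shell inside which CENP-E is the initial motor."""
        return 0.45 * self.a

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be strictly positive")


def ellipsoid_quadratic(p: np.ndarray, g: CellGeometry) -> np.ndarray:
    """(x/a)^2 + (y/b)^2 + (z/c)^2 for points of shape (..., 3)."""
    q = np.asarray(p, dtype=float) / g.semi_axes
    return np.einsum("...i,...i->...", q, q)


def inside_cortex(p: np.ndarray, g: CellGeometry) -> np.ndarray:
    """Strict-interior test; boundary points are *not* inside."""
    return ellipsoid_quadratic(p, g) < 1.0


def max_ray_length(origin: np.ndarray, direction: np.ndarray, g: CellGeometry) -> np.ndarray:
    """Largest t >= 0 with origin + t * direction on the cortex.

    Solves the ray--ellipsoid quadratic; vectorised over leading axes.
    Raises ``ValueError`` if any origin lies outside the cortex (no positive
    root).
    """
    o = np.asarray(origin, dtype=float) / g.semi_axes
    d = np.asarray(direction, dtype=float) / g.semi_axes
    A = np.einsum("...i,...i->...", d, d)
    B = np.einsum("...i,...i->...", o, d)
    C = np.einsum("...i,...i->...", o, o) - 1.0
    if np.any(C >= 0.0):
        raise ValueError("ray origin outside the cortex")
    disc = B * B - A * C
    t = (-B + np.sqrt(disc)) / A
    return t


def confine_to_cortex(p: np.ndarray, g: CellGeometry) -> np.ndarray:
    """Project points outside the cortex radially back onto the boundary.

    Points inside are returned unchanged; the projection scales the position
    vector (about the cell centre) so the result lies exactly on the
    ellipsoid.  This is the hard-repulsion rule for chromosomes.
    """
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr).copy()
    q = ellipsoid_quadratic(pts, g)
    out = q >= 1.0
    if np.any(out):
        pts[out] /= np.sqrt(q[out])[:, None]
    return pts[0] if single else pts


def _confine(p: np.ndarray, g: CellGeometry) -> np.ndarray:
    """In-place-style confinement for an (n, 3) array; returns the array."""
    q = ellipsoid_quadratic(p, g)
    out = q >= 1.0
    if np.any(out):
        p[out] /= np.sqrt(q[out])[:, None]
    return p


def uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n i.i.d. unit vectors uniform on the sphere, shape (n, 3)."""
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_initial_chromosomes(
    n_c: int, g: CellGeometry, rng: np.random.Generator, radius: float | None = None
) -> np.ndarray:
    """Chromosome starting positions: i.i.d. uniform in a ball.

    By default the ball is the nuclear region of radius ``0.65 a`` centred at
    the origin (the configuration just after nuclear envelope breakdown).
    Passing ``radius=g.r_cenpe_shell`` restricts the start to the interpolar
    shell.
    """
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    r = g.r_nucleus if radius is None else radius
    dirs = uniform_directions(rng, n_c)
    radii = r * rng.random(n_c) ** (1.0 / 3.0)
    return dirs * radii[:, None]


# ---------------------------------------------------------------------------
# MT--chromosome predicates
# ---------------------------------------------------------------------------

def segment_point_distance(
    start: np.ndarray, direction: np.ndarray, length: np.ndarray, point: np.ndarray
) -> np.ndarray:
    """Minimum distance from the segment start -> start + length*direction to point.

    ``start``/``direction`` may be (3,) or (n, 3); ``length`` scalar or (n,).
    ``direction`` must be unit length.
    """
    start = np.asarray(start, dtype=float)
    direction = np.asarray(direction, dtype=float)
    rel = np.asarray(point, dtype=float) - start
    t = np.einsum("...i,...i->...", rel, direction)
    t = np.clip(t, 0.0, length)
    closest = start + np.asarray(t)[..., None] * direction
    return np.linalg.norm(np.asarray(point) - closest, axis=-1)


def kinetochore_proximity_test(
    start: np.ndarray, direction: np.ndarray, length: np.ndarray,
    ch_pos: np.ndarray, r_k: float,
) -> np.ndarray:
    """True iff the MT segment passes within r_k of the chromosome centre."""
    return segment_point_distance(start, direction, length, ch_pos) <= r_k


def arm_crossing_test(
    start: np.ndarray, direction: np.ndarray, length: np.ndarray,
    ch_pos: np.ndarray, r_c: float, geometry: str = "disk",
) -> np.ndarray:
    """True iff the MT segment crosses the chromosome arm cross-section.

    With ``geometry="disk"`` (default) the arms are a disk of radius ``r_c``
    centred on the chromosome with normal along x: the segment must cross the
    plane through ``ch_pos`` perpendicular to x at a point within ``r_c`` of
    the centre.  With ``geometry="sphere"`` the cross-section is
    orientation-free: the segment must pass within ``r_c`` of the centre.
    """
    if geometry == "sphere":
        return segment_point_distance(start, direction, length, ch_pos) <= r_c
    start = np.atleast_2d(np.asarray(start, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    length = np.atleast_1d(np.asarray(length, dtype=float))
    ch_pos = np.asarray(ch_pos, dtype=float)
    dx = direction[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ch_pos[0] - start[:, 0]) / dx
    valid = (dx != 0.0) & (t > 0.0) & (t <= length)
    hit = start + t[:, None] * direction
    dist2 = (hit[:, 1] - ch_pos[1]) ** 2 + (hit[:, 2] - ch_pos[2]) ** 2
    res = valid & (dist2 <= r_c * r_c)
    return res if res.size > 1 else bool(res[0])


def tip_contact_side(
    tip: np.ndarray, ch_pos: np.ndarray, r_k: float, mt_pole: int | np.ndarray = 0
) -> np.ndarray:
    """Which kinetochore hemisphere an MT tip touches.

    Returns ``NONE`` (0) if the tip is farther than ``r_k`` from the
    chromosome centre, else ``LEFT`` (-1) for a contact with negative x-offset
    (the hemisphere facing pole 0) or ``RIGHT`` (+1).  An exactly-zero offset
    is broken towards the hemisphere facing the MT's own pole.
    """
    tip = np.atleast_2d(np.asarray(tip, dtype=float))
    rel = tip - np.asarray(ch_pos, dtype=float)
    near = np.einsum("ij,ij->i", rel, rel) <= r_k * r_k
    side = np.sign(rel[:, 0]).astype(np.int64)
    tie = side == 0
    if np.any(tie):
        pole_side = np.where(np.atleast_1d(mt_pole) == 0, LEFT, RIGHT)
        side = np.where(tie, np.broadcast_to(pole_side, side.shape), side)
    res = np.where(near, side, NONE)
    return res if res.size > 1 else int(res[0])
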