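"""Projection-direction arithmetic and the constrained five-parameter search space.

Angle conventions
-----------------
A particle orientation is given by ZYZ intrinsic Euler angles (SPIDER
convention): rotate by ``phi`` about z, ``theta`` about the new y, ``psi``
about the new z; the projection integrates along the final z axis.  The
projection direction (the camera position on the unit sphere) is

    e_r = (sin(theta) cos(phi), sin(theta) sin(phi), cos(theta)),

``psi`` is the in-plane rotation of the camera measured against the meridian
through the direction point, and ``(x, y)`` shift the projected object by
(+x, +y) pixels in the image.  All angles are degrees externally; trig is
done in double precision radians internally.

At the poles (theta = 0 or 180) the meridian reference is undefined; this
module adopts the phi = 0 meridian limit, so the total in-plane angle there
is ``psi + phi`` (theta = 0) and the decomposition returns phi = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidParameterError, ResourceLimitError

#: surface area of the unit sphere in square degrees
SPHERE_SQUARE_DEGREES = 129600.0 / math.pi  # = 4*pi*(180/pi)^2 ~ 41252.96


class ProjectionDirection(NamedTuple):
    """A point on the unit sphere given as (azimuth phi, polar theta) in degrees."""

    phi: float
    theta: float


class OrientationParams(NamedTuple):
    """The five projection parameters of one particle or one module."""

    phi: float
    theta: float
    psi: float
    x: float = 0.0
    y: float = 0.0

    @property
    def direction(self) -> ProjectionDirection:
        return ProjectionDirection(self.phi, self.theta)


@dataclass(frozen=True)
class SearchRange:
    """Local search specification around a preliminary orientation.

    alpha0 : cone semi-angle for the projection direction, degrees
    d1, t1 : in-plane rotation step (degrees) and half-extent (steps)
    d2, t2 : shift step (pixels) and half-extent (steps)
    directions : (n, 2) array of (phi, theta) rows, the global direction set D
    """

    alpha0: float
    d1: float
    t1: int
    d2: float
    t2: int
    directions: np.ndarray = field(repr=False)

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 2 or d.shape[0] == 0:
            raise InvalidParameterError("directions must be a nonempty (n, 2) array")
        object.__setattr__(self, "directions", d)
        if not (self.alpha0 >= 0 and self.d1 > 0 and self.d2 > 0):
            raise InvalidParameterError("alpha0 must be >= 0 and steps positive")
        if self.t1 < 0 or self.t2 < 0 or self.t1 != int(self.t1) or self.t2 != int(self.t2):
            raise InvalidParameterError("t1, t2 must be non-negative integers")


def _check_direction(direction) -> tuple[float, float]:
    phi, theta = float(direction[0]), float(direction[1])
    if not (math.isfinite(phi) and math.isfinite(theta)):
        raise InvalidParameterError("direction angles must be finite")
    if not 0.0 <= theta <= 180.0:
        raise InvalidParameterError(f"theta must lie in [0, 180], got {theta}")
    return phi, theta


def direction_to_vector(direction) -> np.ndarray:
    """Unit vector e_r of a projection direction."""
    phi, theta = _check_direction(direction)
    p, t = math.radians(phi), math.radians(theta)
    return np.array([math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)])


def vector_to_direction(vec) -> ProjectionDirection:
    """Inverse of :func:`direction_to_vector`; phi reduced to [0, 360)."""
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise InvalidParameterError("cannot convert zero/non-finite vector")
    v = v / n
    theta = math.degrees(math.acos(min(1.0, max(-1.0, v[2]))))
    phi = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return ProjectionDirection(phi, theta)


def span_angle(dir0, dir1) -> float:
    """Great-circle angle between two projection directions, degrees in [0, 180]."""
    e0 = direction_to_vector(dir0)
    e1 = direction_to_vector(dir1)
    c = float(np.dot(e0, e1))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def euler_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """World-to-camera rotation R = Rz(psi) Ry(theta) Rz(phi).

    ``R @ e_r == (0, 0, 1)``: the matrix brings the viewing direction onto
    the projection (z) axis.
    """
    return _rz(psi) @ _ry(theta) @ _rz(phi)


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """ZYZ decomposition; phi, psi in [0, 360), theta in [0, 180].

    At the poles the phi = 0 convention is used.
    """
    ct = min(1.0, max(-1.0, float(R[2, 2])))
    theta = math.degrees(math.acos(ct))
    if min(theta, 180.0 - theta) < 1e-7:
        phi = 0.0
        psi = math.degrees(math.atan2(R[0, 1], R[0, 0])) % 360.0
        if theta > 90.0:  # theta = 180: R = Rz(psi) Ry(180) Rz(phi)
            psi = math.degrees(math.atan2(-R[0, 1], -R[0, 0])) % 360.0
    else:
        phi = math.degrees(math.atan2(R[2, 1], R[2, 0])) % 360.0
        psi = math.degrees(math.atan2(R[1, 2], -R[0, 2])) % 360.0
    return phi, theta, psi


def psi_from_matrix(R: np.ndarray, phi: float, theta: float) -> float:
    """In-plane angle psi such that R = Rz(psi) Ry(theta) Rz(phi), for known
    (phi, theta).  Well defined at the poles, where phi and psi are coupled."""
    M = R @ _rz(-phi) @ _ry(-theta)  # = Rz(psi)
    return math.degrees(math.atan2(M[0, 1], M[0, 0])) % 360.0


def generate_direction_set(
    spacing_deg: float, hemisphere: bool = False, max_points: int = 2_000_000
) -> np.ndarray:
    """Quasi-uniform covering of the sphere by a deterministic spiral.

    Uses the Saff–Kuijlaars generalized spiral; the number of points is the
    area-based count ``ceil(41253 / spacing**2)`` so that neighbouring points
    are roughly ``spacing_deg`` apart.  With ``hemisphere=True`` only the
    upper half (theta <= 90) is returned.

    Returns an (n, 2) array of (phi, theta) rows in degrees.
    """
    if not (spacing_deg > 0 and math.isfinite(spacing_deg)):
        raise InvalidParameterError("spacing_deg must be positive and finite")
    n = max(int(math.ceil(SPHERE_SQUARE_DEGREES / spacing_deg**2)), 2)
    if n > max_points:
        raise ResourceLimitError(
            f"direction set of {n} points exceeds the cap of {max_points}"
        )
    k = np.arange(1, n + 1, dtype=float)
    h = -1.0 + 2.0 * (k - 1.0) / (n - 1.0)
    theta = np.degrees(np.arccos(np.clip(h, -1.0, 1.0)))
    phi = np.zeros(n)
    for i in range(1, n - 1):
        phi[i] = phi[i - 1] + 3.6 / math.sqrt(n * (1.0 - h[i] ** 2))
    phi = np.degrees(phi) % 360.0
    dirs = np.column_stack([phi, theta])
    if hemisphere:
        dirs = dirs[theta <= 90.0]
    return dirs


def span_angles_to(dirs: np.ndarray, dir0) -> np.ndarray:
    """Vectorized span angle (degrees) from each row of ``dirs`` to ``dir0``."""
    d = np.asarray(dirs, dtype=float)
    e0 = direction_to_vector(dir0)
    t = np.radians(d[:, 1])
    p = np.radians(d[:, 0])
    vecs = np.column_stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    return np.degrees(np.arccos(np.clip(vecs @ e0, -1.0, 1.0)))


def constrain_directions(directions, dir0, alpha0: float) -> np.ndarray:
    """Members of the direction set within ``alpha0`` degrees of ``dir0``.

    The preliminary direction itself is always part of the result: a member
    coincident with it (span < 1e-7 deg) is replaced by the exact ``dir0``
    angles, otherwise ``dir0`` is appended, so the result is never empty and
    contains the preliminary direction exactly once.
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[0] == 0:
        raise InvalidParameterError("direction set must be a nonempty (n, 2) array")
    phi0, theta0 = _check_direction(dir0)
    spans = span_angles_to(d, dir0)
    sel = d[spans <= alpha0 + 1e-12].copy()
    sel_spans = spans[spans <= alpha0 + 1e-12]
    # arccos of a dot product cannot resolve spans below ~1e-6 deg, so also
    # treat bit-identical angle pairs as coincident
    exact = (sel[:, 0] == phi0) & (sel[:, 1] == theta0)
    coincident = np.nonzero((sel_spans < 1e-7) | exact)[0]
    if coincident.size:
        sel[coincident[0]] = (phi0, theta0)
        if coincident.size > 1:
            sel = np.delete(sel, coincident[1:], axis=0)
    else:
        sel = np.vstack([sel, [phi0, theta0]])
    return sel


def transported_psi(dir0, psi0: float, dir_i) -> float:
    """Parallel transport of the in-plane angle from ``dir0`` to ``dir_i``.

    Moves the camera along the great-circle arc between the two directions
    while keeping its angle with the arc fixed, and returns the apparent
    in-plane angle psi_i at the new direction, reduced to [0, 360).  When the
    two directions and the pole lie on one great circle this reproduces the
    closed form psi_i = phi_0 + psi_0 - phi_i.  Antipodal pairs are rejected
    (the connecting arc is not unique).
    """
    phi0, theta0 = _check_direction(dir0)
    phii, thetai = _check_direction(dir_i)
    if not math.isfinite(psi0):
        raise InvalidParameterError("psi0 must be finite")
    e0 = direction_to_vector(dir0)
    ei = direction_to_vector(dir_i)
    c = min(1.0, max(-1.0, float(np.dot(e0, ei))))
    if c <= math.cos(math.radians(180.0 - 1e-9)):
        raise InvalidParameterError("antipodal directions: transport is ill-posed")
    R0 = euler_matrix(phi0, theta0, psi0)
    axis = np.cross(e0, ei)
    norm = np.linalg.norm(axis)
    if norm < 1e-15:
        Ri = R0  # same direction; only the (phi, psi) split may differ
    else:
        axis = axis / norm
        ang = math.acos(c)
        K = np.array(
            [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
        )
        # active rotation taking e0 to ei (Rodrigues)
        Q = np.eye(3) + math.sin(ang) * K + (1.0 - math.cos(ang)) * (K @ K)
        Ri = R0 @ Q.T
    return psi_from_matrix(Ri, phii, thetai)


def build_search_grid(
    params0: OrientationParams, search: SearchRange, max_size: int = 2_000_000
) -> list[OrientationParams]:
    """Cartesian product of constrained directions, transported-psi grid and
    shift grids, centered on the preliminary parameters.

    The grid has exactly ``len(D_constrained) * (2 t1 + 1) * (2 t2 + 1)**2``
    entries and contains ``params0`` exactly once, so a search over it can
    never score below the preliminary parameters.
    """
    p0 = OrientationParams(*params0)
    dirs = constrain_directions(search.directions, p0.direction, search.alpha0)
    n_total = len(dirs) * (2 * search.t1 + 1) * (2 * search.t2 + 1) ** 2
    if n_total > max_size:
        raise ResourceLimitError(f"search grid of {n_total} entries exceeds cap {max_size}")
    psi_steps = search.d1 * np.arange(-search.t1, search.t1 + 1)
    shift_steps = search.d2 * np.arange(-search.t2, search.t2 + 1)
    grid: list[OrientationParams] = []
    for phi_i, theta_i in dirs:
        psi_c = transported_psi(p0.direction, p0.psi, (phi_i, theta_i))
        if abs(phi_i - p0.phi) < 1e-12 and abs(theta_i - p0.theta) < 1e-12:
            psi_c = p0.psi  # keep the preliminary point bit-exact
        for dpsi in psi_steps:
            for dx in shift_steps:
                for dy in shift_steps:
                    grid.append(
                        OrientationParams(
                            phi_i, theta_i, psi_c + dpsi, p0.x + dx, p0.y + dy
                        )
                    )
    return grid
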