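"""Body-axis geometry: spline centre line, (s, t) body coordinates, straightening.

The worm's body axis is represented as a smooth curve fitted through manually
annotated centre-line points (anterior first).  Positions are expressed in
body coordinates: ``s``, the arc length along the anteroposterior (A-P) axis
in micrometres, and ``t``, the signed perpendicular distance along the
dorsoventral (D-V) axis, with ``t < 0`` on the ventral side.  The ventral
side is identified from an annotated anatomical landmark (the gonad in
L2-L3 animals, the vulva in L3-L4 animals).

The same transform that maps camera coordinates to (s, t) is used to resample
images onto the body grid, producing computationally straightened images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

__all__ = [
    "BodyAxis",
    "BodyPoint",
    "PixelGrid",
    "fit_body_axis",
    "to_body_coords",
    "from_body_coords",
    "straighten_image",
    "body_length",
]

# dense samples per control-point segment used for arc-length integration
_SAMPLES_PER_SEGMENT = 500


@dataclass(frozen=True)
class PixelGrid:
    """Isotropic camera pixel grid.

    Coordinates are 0-based with pixel centres at integer pixel indices, so a
    camera position ``(x, y)`` in micrometres lives at image index
    ``[y / pixel_size, x / pixel_size]``.
    """

    pixel_size: float  # um per pixel

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def to_um(self, px: np.ndarray) -> np.ndarray:
        return np.asarray(px, dtype=float) * self.pixel_size

    def to_px(self, um: np.ndarray) -> np.ndarray:
        return np.asarray(um, dtype=float) / self.pixel_size


@dataclass(frozen=True)
class BodyPoint:
    """A position in body coordinates: arc length ``s`` (um) along the A-P
    axis and signed D-V offset ``t`` (um, negative ventral)."""

    s: float
    t: float
    frame_index: int = 0


@dataclass
class BodyAxis:
    """Arc-length parameterized body centre line in the camera frame.

    ``curve(s)`` maps arc length ``s`` in ``[0, L]`` to a 2-D camera position
    in micrometres.  ``ventral_sign`` flips the +90-degree tangent normal so
    that the annotated ventral landmark projects to ``t < 0``.
    """

    control_points: np.ndarray  # (n, 2) um, anterior first
    ventral_sign_reference: np.ndarray  # (2,) um
    ventral_sign: float = 1.0
    _spline_x: CubicSpline = field(repr=False, default=None)
    _spline_y: CubicSpline = field(repr=False, default=None)
    # dense arc-length table: chord parameter u vs cumulative arc length
    _u_dense: np.ndarray = field(repr=False, default=None)
    _arc_dense: np.ndarray = field(repr=False, default=None)
    _points_dense: np.ndarray = field(repr=False, default=None)

    @property
    def length(self) -> float:
        """Body length L in micrometres."""
        return float(self._arc_dense[-1])

    # -- parameter bookkeeping -------------------------------------------
    def _u_of_s(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        return np.interp(s, self._arc_dense, self._u_dense)

    def _s_of_u(self, u: np.ndarray) -> np.ndarray:
        return np.interp(u, self._u_dense, self._arc_dense)

    def _eval_u(self, u) -> np.ndarray:
        return np.stack([self._spline_x(u), self._spline_y(u)], axis=-1)

    def _deriv_u(self, u, nu: int = 1) -> np.ndarray:
        return np.stack(
            [self._spline_x(u, nu=nu), self._spline_y(u, nu=nu)], axis=-1
        )

    # -- public curve evaluation -----------------------------------------
    def curve(self, s) -> np.ndarray:
        """Camera position (um) at arc length ``s``; vectorized."""
        return self._eval_u(self._u_of_s(np.asarray(s, dtype=float)))

    def tangent(self, s) -> np.ndarray:
        """Unit tangent at arc length ``s`` (anterior to posterior)."""
        d = self._deriv_u(self._u_of_s(np.asarray(s, dtype=float)))
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def normal(self, s) -> np.ndarray:
        """Unit normal at ``s``, oriented so the ventral side has t < 0."""
        tan = self.tangent(s)
        n = np.stack([-tan[..., 1], tan[..., 0]], axis=-1)
        return self.ventral_sign * n

    def curvature(self, s) -> np.ndarray:
        """Unsigned curvature kappa(s) in 1/um."""
        u = self._u_of_s(np.asarray(s, dtype=float))
        d1 = self._deriv_u(u, 1)
        d2 = self._deriv_u(u, 2)
        cross = d1[..., 0] * d2[..., 1] - d1[..., 1] * d2[..., 0]
        speed = np.linalg.norm(d1, axis=-1)
        return np.abs(cross) / speed**3


def fit_body_axis(points, ventral_marker) -> BodyAxis:
    """Fit the body-axis spline through annotated centre-line points.

    Parameters
    ----------
    points
        Ordered (n, 2) centre-line points in micrometres, anterior first;
        at least 4 points, consecutive points distinct.
    ventral_marker
        2-D point (um) on the ventral side of the animal (gonad or vulva),
        used only to orient the sign of ``t``.

    Returns
    -------
    BodyAxis with an interpolating cubic spline, reparameterized by arc
    length through dense polyline integration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 4:
        raise ValueError("insufficient centre-line points (need at least 4)")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive centre-line points")

    # chord-length parameterization, then cubic interpolation per coordinate
    u_knots = np.concatenate([[0.0], np.cumsum(seg)])
    sx = CubicSpline(u_knots, pts[:, 0])
    sy = CubicSpline(u_knots, pts[:, 1])

    n_dense = _SAMPLES_PER_SEGMENT * (len(pts) - 1) + 1
    u_dense = np.linspace(0.0, u_knots[-1], n_dense)
    pd = np.stack([sx(u_dense), sy(u_dense)], axis=-1)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pd, axis=0), axis=1))]
    )

    axis = BodyAxis(
        control_points=pts,
        ventral_sign_reference=np.asarray(ventral_marker, dtype=float),
        _spline_x=sx,
        _spline_y=sy,
        _u_dense=u_dense,
        _arc_dense=arc,
        _points_dense=pd,
    )
    # orient the normal: the ventral landmark must project to t < 0
    bp = to_body_coords(axis.ventral_sign_reference, axis)
    if bp.t > 0:
        axis.ventral_sign = -1.0
    return axis


def body_length(axis: BodyAxis) -> float:
    """Body length: the arc length of the fitted centre line (um)."""
    return axis.length


def _project_u(axis: BodyAxis, p: np.ndarray) -> float:
    """Chord parameter of the curve point nearest to camera point ``p``.

    Coarse minimum over the dense polyline, then Newton polish on the
    orthogonality condition (p - c(u)) . c'(u) = 0.  Ties (equidistant dense
    samples at a fold) resolve to the smallest u via argmin.
    """
    d2 = np.sum((axis._points_dense - p) ** 2, axis=1)
    i = int(np.argmin(d2))
    u = axis._u_dense[i]
    lo = axis._u_dense[max(i - 1, 0)]
    hi = axis._u_dense[min(i + 1, len(axis._u_dense) - 1)]
    for _ in range(30):
        c = axis._eval_u(u)
        d1 = axis._deriv_u(u, 1)
        dd = axis._deriv_u(u, 2)
        g = float(np.dot(p - c, d1))
        gp = float(-np.dot(d1, d1) + np.dot(p - c, dd))
        if gp == 0.0:
            break
        step = g / gp
        u_new = min(max(u - step, lo), hi)
        if abs(u_new - u) < 1e-13 * max(1.0, abs(u)):
            u = u_new
            break
        u = u_new
    return float(np.clip(u, axis._u_dense[0], axis._u_dense[-1]))


def to_body_coords(p, axis: BodyAxis, frame_index: int = 0) -> BodyPoint:
    """Convert a camera point (um) to body coordinates (s, t).

    ``s`` minimizes the distance from ``p`` to the curve; ``|t|`` is that
    minimal distance, negative on the ventral side.  Points projecting beyond
    the head or tail clamp to s=0 or s=L.
    """
    p = np.asarray(p, dtype=float)
    u = _project_u(axis, p)
    s = float(axis._s_of_u(u))
    c = axis._eval_u(u)
    delta = p - c
    n = axis.normal(s)
    t = float(np.dot(delta, n))
    # beyond the endpoints the residual has a tangential component; keep the
    # full distance as |t| with the sign of the normal component
    dist = float(np.linalg.norm(delta))
    if dist > abs(t) + 1e-12:
        t = np.copysign(dist, t if t != 0 else 1.0)
    return BodyPoint(s=s, t=t, frame_index=frame_index)


def from_body_coords(bp: BodyPoint, axis: BodyAxis) -> np.ndarray:
    """Camera position (um) of body point ``(s, t)``: curve(s) + t * n(s)."""
    if not (0.0 <= bp.s <= axis.length + 1e-9):
        raise ValueError(f"s={bp.s} outside [0, {axis.length}]")
    return axis.curve(bp.s) + bp.t * axis.normal(bp.s)


def straighten_image(
    image: np.ndarray,
    axis: BodyAxis,
    half_width: float,
    grid: PixelGrid,
) -> np.ndarray:
    """Resample an image onto the (s, t) body grid.

    Output column ``c`` is arc length ``s = c * pixel_size``; output row ``r``
    is D-V offset ``t = (r - r0) * pixel_size`` with ``r0 = height // 2``, so
    ventral (t < 0) is at the top of the straightened image and the centre
    line lies on row ``r0``.  Bilinear interpolation; samples outside the
    camera field of view are filled with 0.
    """
    if not half_width > 0:
        raise ValueError("half_width must be positive")
    image = np.asarray(image, dtype=float)
    px = grid.pixel_size
    width = int(np.ceil(axis.length / px))
    height = int(np.ceil(2 * half_width / px))
    r0 = height // 2

    s_vals = np.arange(width) * px
    t_vals = (np.arange(height) - r0) * px
    centres = axis.curve(s_vals)  # (W, 2)
    normals = axis.normal(s_vals)  # (W, 2)
    # camera positions for every (row, col) of the straightened image
    pos = centres[None, :, :] + t_vals[:, None, None] * normals[None, :, :]
    rows = pos[..., 1] / px
    cols = pos[..., 0] / px
    return map_coordinates(
        image, [rows, cols], order=1, mode="constant", cval=0.0
    )


def straightened_index(
    bp: BodyPoint, half_width: float, grid: PixelGrid
) -> tuple[float, float]:
    """(row, col) in a straightened image corresponding to body point ``bp``."""
    px = grid.pixel_size
    height = int(np.ceil(2 * half_width / px))
    return bp.t / px + height // 2, bp.s / px


def projection_ambiguous(axis: BodyAxis, p, rel_tol: float = 1e-6) -> bool:
    """True when several well-separated arc lengths are (near-)equidistant
    from ``p`` (the point sits on the medial axis of a bend); the projection
    then returns the smallest such s."""
    p = np.asarray(p, dtype=float)
    d = np.linalg.norm(axis._points_dense - p, axis=1)
    dmin = d.min()
    close = np.flatnonzero(d <= dmin * (1 + rel_tol) + 1e-12)
    if len(close) < 2:
        return False
    ambiguous = bool(np.any(np.diff(close) > 2))
    if ambiguous:
        warnings.warn(
            "point is near the medial axis of a bend; projection ties broken "
            "toward the smallest s",
            stacklevel=2,
        )
    return ambiguous
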