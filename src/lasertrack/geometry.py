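"""Pointing geometry: image-plane to cage-floor mapping and pan/tilt targeting.

A fixed overhead camera views the planar cage floor, so image pixels and
floor coordinates are related by a plane-to-plane homography.  The laser is
carried by a two-axis gimbal mounted above the floor; pointing it at a floor
location is a closed-form trigonometric conversion (horizontal bearing ->
pan, horizontal-distance/height -> tilt), and the inverse -- where the beam
actually lands -- is a ray/plane intersection.

Conventions
-----------
* Pixel coordinates: ``u`` rightward (column), ``v`` downward (row),
  pixel centres at integer coordinates, origin at the top-left pixel centre.
* Floor coordinates: metres, ``z = 0`` on the floor, ``z`` up.
* ``pan_deg``: rotation about the vertical axis, counter-clockwise viewed
  from above, measured from the gimbal's reference axis (the direction the
  yaw encoder was zeroed against, parallel to the mounting frame).
  Reported in ``(-180, 180]``.
* ``tilt_deg``: inclination of the beam from straight down (nadir);
  ``0`` means pointing vertically at the floor beneath the mount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "CameraModel",
    "GimbalModel",
    "GimbalPose",
    "calibrate_homography",
    "pixel_to_arena",
    "arena_to_pixel",
    "arena_to_gimbal",
    "laser_spot",
]


class CalibrationError(ValueError):
    """Raised when a homography cannot be estimated from the correspondences."""


@dataclass(frozen=True)
class CameraModel:
    """Planar homography mapping image pixels (u, v) to floor metres (x, y).

    ``homography`` is the 3x3 pixel->floor map, normalised so its
    bottom-right element is 1.  The model must be invertible; the floor->pixel
    direction uses the matrix inverse.
    """

    homography: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.homography, dtype=float)
        if H.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {H.shape}")
        if abs(np.linalg.det(H)) < 1e-15:
            raise ValueError("homography is singular")
        object.__setattr__(self, "homography", H)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.homography)

    def to_dict(self) -> dict:
        return {"homography": self.homography.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(homography=np.asarray(d["homography"], dtype=float))


def _apply_homography(H: np.ndarray, a: float, b: float) -> tuple[float, float]:
    p = H @ np.array([a, b, 1.0])
    w = p[2]
    if abs(w) < 1e-12 * max(abs(p[0]), abs(p[1]), 1.0):
        raise ValueError("point projects to the plane at infinity (w ~ 0)")
    return float(p[0] / w), float(p[1] / w)


def pixel_to_arena(model: CameraModel, u: float, v: float) -> tuple[float, float]:
    """Map an image point (pixels) to floor coordinates (metres)."""
    return _apply_homography(model.homography, u, v)


def arena_to_pixel(model: CameraModel, x: float, y: float) -> tuple[float, float]:
    """Map a floor point (metres) to image coordinates (pixels)."""
    return _apply_homography(model.inverse, x, y)


def _normalize_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Hartley normalisation: centroid at origin, mean distance sqrt(2)
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = math.sqrt(2) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    ones = np.ones((len(pts), 1))
    pn = (T @ np.hstack([pts, ones]).T).T[:, :2]
    return pn, T


def calibrate_homography(pixel_points, arena_points) -> CameraModel:
    """Estimate the pixel->floor homography from point correspondences.

    Uses the normalised direct linear transform; with more than four
    correspondences the result is the least-squares solution.  At least
    four correspondences in general position are required.

    Raises
    ------
    CalibrationError
        Fewer than 4 points, mismatched lengths, or a degenerate
        configuration (e.g. collinear points).
    """
    P = np.asarray(pixel_points, dtype=float).reshape(-1, 2)
    A_ = np.asarray(arena_points, dtype=float).reshape(-1, 2)
    if len(P) != len(A_):
        raise CalibrationError("pixel and arena point counts differ")
    if len(P) < 4:
        raise CalibrationError(f"need at least 4 correspondences, got {len(P)}")

    Pn, Tp = _normalize_points(P)
    An, Ta = _normalize_points(A_)

    rows = []
    for (u, v), (x, y) in zip(Pn, An):
        rows.append([u, v, 1, 0, 0, 0, -x * u, -x * v, -x])
        rows.append([0, 0, 0, u, v, 1, -y * u, -y * v, -y])
    M = np.asarray(rows)
    _, s, Vt = np.linalg.svd(M)
    # two vanishing singular values => the solution is not unique
    if len(s) >= 2 and s[-2] < 1e-9 * s[0]:
        raise CalibrationError("degenerate correspondence configuration (rank deficient)")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Ta) @ Hn @ Tp
    if abs(H[2, 2]) < 1e-12 * np.abs(H).max():
        raise CalibrationError("homography cannot be normalised (h33 ~ 0)")
    H = H / H[2, 2]
    if abs(np.linalg.det(H)) < 1e-15:
        raise CalibrationError("estimated homography is singular")
    return CameraModel(homography=H)


@dataclass(frozen=True)
class GimbalModel:
    """Geometry and kinematic limits of the laser mount.

    The gimbal hangs at ``(mount_x_m, mount_y_m)`` in floor coordinates,
    ``mount_z_m`` above the floor.  ``pan_zero_axis`` is the in-plane
    direction pan is measured from (the yaw reference, parallel to the
    mounting frame).  ``max_slew_deg_per_s`` bounds each axis' angular
    velocity -- the abstraction of the stabilised servo loop.

    The default mount sits at a top corner of the gantry frame rather than
    over the arena centre: a pan/tilt head mounted directly above the area
    the animal occupies suffers the keyhole singularity (pan demand flips
    by up to 180 degrees as the target crosses nadir, which no finite slew
    rate can follow), whereas a corner mount keeps the whole floor inside a
    smooth pan/tilt range.
    """

    mount_x_m: float = 0.205
    mount_y_m: float = 0.205
    mount_z_m: float = 0.33
    pan_zero_axis: tuple[float, float] = (1.0, 0.0)
    max_slew_deg_per_s: float = 300.0
    pan_limits_deg: tuple[float, float] = (-180.0, 180.0)
    tilt_limits_deg: tuple[float, float] = (0.0, 85.0)

    def validate(self) -> list[str]:
        errs = []
        if not self.mount_z_m > 0:
            errs.append("mount_z_m: must be > 0")
        if math.hypot(*self.pan_zero_axis) == 0:
            errs.append("pan_zero_axis: must be a non-zero direction")
        if not self.max_slew_deg_per_s > 0:
            errs.append("max_slew_deg_per_s: must be > 0")
        if not self.pan_limits_deg[0] <= self.pan_limits_deg[1]:
            errs.append("pan_limits_deg: empty interval")
        lo, hi = self.tilt_limits_deg
        if not (lo <= hi and lo >= 0.0 and hi < 90.0):
            errs.append("tilt_limits_deg: must be a non-empty interval within [0, 90)")
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


@dataclass(frozen=True)
class GimbalPose:
    """Pan/tilt angles of the gimbal, degrees.

    ``clamped`` flags a commanded pose that had to be clipped to the
    model's axis limits (the requested floor target was outside the
    reachable cone).
    """

    pan_deg: float
    tilt_deg: float
    clamped: bool = False


def arena_to_gimbal(
    model: GimbalModel, x: float, y: float, prev_pan_deg: float = 0.0
) -> GimbalPose:
    """Pan/tilt pose that points the beam at floor point ``(x, y)``.

    With horizontal offset ``d`` from the point beneath the mount,
    ``tilt = atan(d / mount_z)`` and pan is the bearing of the offset from
    the reference axis, counter-clockwise from above, in ``(-180, 180]``.
    Directly beneath the mount (``d == 0``) the bearing is undefined and
    the previous pan is kept, so trajectories through nadir cause no pan
    jump.  The result is clamped to the model's limits with
    ``clamped=True`` when out of range.
    """
    dx = x - model.mount_x_m
    dy = y - model.mount_y_m
    d = math.hypot(dx, dy)
    tilt = math.degrees(math.atan2(d, model.mount_z_m))
    if d == 0.0:
        pan = prev_pan_deg
    else:
        ax, ay = model.pan_zero_axis
        pan = math.degrees(math.atan2(ax * dy - ay * dx, ax * dx + ay * dy))
        if pan <= -180.0:  # atan2 returns (-pi, pi]; keep (-180, 180]
            pan += 360.0

    clamped = False
    plo, phi = model.pan_limits_deg
    tlo, thi = model.tilt_limits_deg
    if not plo <= pan <= phi:
        pan = min(max(pan, plo), phi)
        clamped = True
    if not tlo <= tilt <= thi:
        tilt = min(max(tilt, tlo), thi)
        clamped = True
    return GimbalPose(pan_deg=pan, tilt_deg=tilt, clamped=clamped)


def laser_spot(model: GimbalModel, pose: GimbalPose) -> tuple[float, float]:
    """Floor point hit by the beam for a given pose.

    The ray leaves the mount with direction
    ``(sin t cos p, sin t sin p, -cos t)`` (angles relative to the pan
    reference axis) and is intersected with the floor plane ``z = 0``:
    ``spot = mount_xy + mount_z * tan(tilt) * (cos pan, sin pan)``.

    Raises
    ------
    ValueError
        ``tilt >= 90`` degrees: the beam is horizontal or upward and never
        reaches the floor.
    """
    if pose.tilt_deg >= 90.0:
        raise ValueError(f"tilt {pose.tilt_deg} deg >= 90: beam does not reach the floor")
    r = model.mount_z_m * math.tan(math.radians(pose.tilt_deg))
    ax, ay = model.pan_zero_axis
    n = math.hypot(ax, ay)
    ax, ay = ax / n, ay / n
    c = math.cos(math.radians(pose.pan_deg))
    s = math.sin(math.radians(pose.pan_deg))
    # rotate the reference axis by pan (CCW from above)
    ux = c * ax - s * ay
    uy = s * ax + c * ay
    return model.mount_x_m + r * ux, model.mount_y_m + r * uy
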