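"""Synthetic overhead-camera scenes with exact ground truth.

Emulates the camera feed of a laser-targeting rig watching a single mouse
in a dark-floored 20 x 20 cm cage: a grey elliptical body carrying a
red circular pen mark on its back, moving as a bounded random walk, imaged
with additive Gaussian sensor noise.  Occlusion intervals blank the marker
(as when the animal rears or grooms over the mark) without moving it.

Every frame comes with the exact sub-pixel image position of the marker
centre, which is what tracking accuracy is measured against.

Coordinate conventions match :mod:`lasertrack.geometry`: pixel centres at
integer (u, v), u rightward / v downward, origin top-left; a floor point
``x`` metres from the left wall projects to ``u = x * (W / arena_width) - 0.5``
so that the arena exactly spans the pixel grid footprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .files import atomic_write_bytes
from .geometry import CameraModel

__all__ = [
    "SceneConfig",
    "MotionParams",
    "MotionState",
    "GroundTruthRecord",
    "OutOfArenaError",
    "step_motion",
    "initial_state",
    "render_frame",
    "iter_scene",
    "generate_dataset",
    "add_salt_pepper",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = [
    "frame_index",
    "time_s",
    "marker_x_m",
    "marker_y_m",
    "marker_u_px",
    "marker_v_px",
    "occluded",
]


class OutOfArenaError(ValueError):
    """A position fell outside the cage floor."""


@dataclass(frozen=True)
class SceneConfig:
    """Static description of the synthetic cage scene.

    Defaults model the real rig: a 20 x 20 cm black acrylic cage floor
    filling a 640 x 640 px overhead view (32 px/cm), a grey mouse-sized
    body (~7.5 x 3.5 cm) and a ~1.5 cm red pen circle on its back.
    """

    arena_width_m: float = 0.20
    arena_height_m: float = 0.20
    image_width_px: int = 640
    image_height_px: int = 640
    background_gray: int = 30
    body_axes_px: tuple[float, float] = (120.0, 56.0)
    body_gray: int = 110
    marker_radius_px: float = 24.0
    marker_rgb: tuple[int, int, int] = (200, 30, 30)
    noise_sigma: float = 3.0
    occlusion_intervals: tuple[tuple[int, int], ...] = ()
    fps: float = 20.0
    n_frames: int = 200
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if not (self.arena_width_m > 0 and self.arena_height_m > 0):
            errs.append("arena dimensions: must be > 0")
        if not (self.image_width_px >= 1 and self.image_height_px >= 1):
            errs.append("image dimensions: must be >= 1 px")
        if not self.marker_radius_px >= 1:
            errs.append("marker_radius_px: must be >= 1")
        if self.noise_sigma < 0:
            errs.append("noise_sigma: must be >= 0")
        for g in (self.background_gray, self.body_gray):
            if not 0 <= g <= 255:
                errs.append("gray levels: must be in [0, 255]")
                break
        if not all(0 <= c <= 255 for c in self.marker_rgb):
            errs.append("marker_rgb: channels must be in [0, 255]")
        if not self.fps > 0:
            errs.append("fps: must be > 0")
        if self.n_frames < 0:
            errs.append("n_frames: must be >= 0")
        for iv in self.occlusion_intervals:
            if not (0 <= iv[0] < iv[1] <= self.n_frames):
                errs.append(
                    f"occlusion_intervals: [{iv[0]}, {iv[1]}) not within [0, {self.n_frames})"
                )
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))

    # -- projection between floor metres and image pixels ------------------

    @property
    def px_per_m(self) -> tuple[float, float]:
        return (
            self.image_width_px / self.arena_width_m,
            self.image_height_px / self.arena_height_m,
        )

    def arena_to_pixel(self, x_m: float, y_m: float) -> tuple[float, float]:
        sx, sy = self.px_per_m
        return x_m * sx - 0.5, y_m * sy - 0.5

    def camera_model(self) -> CameraModel:
        """Exact pixel->floor homography of this synthetic camera."""
        sx, sy = self.px_per_m
        H = np.array([[1 / sx, 0, 0.5 / sx], [0, 1 / sy, 0.5 / sy], [0, 0, 1.0]])
        return CameraModel(homography=H)

    def is_occluded(self, frame_index: int) -> bool:
        return any(a <= frame_index < b for a, b in self.occlusion_intervals)


@dataclass(frozen=True)
class MotionParams:
    """Bounded stochastic motion of the animal on the cage floor.

    The velocity follows an Ornstein-Uhlenbeck process: it relaxes towards
    zero with time constant ``relaxation_time_s`` and is driven by white
    noise such that each component's stationary standard deviation is
    ``speed_scale_m_per_s``.  Positions reflect off the walls at
    ``boundary_margin_m`` (roughly half a body width), flipping the
    corresponding velocity component.
    """

    speed_scale_m_per_s: float = 0.05
    relaxation_time_s: float = 1.0
    boundary_margin_m: float = 0.01

    def validate(self) -> list[str]:
        errs = []
        if self.speed_scale_m_per_s < 0:
            errs.append("speed_scale_m_per_s: must be >= 0")
        if not self.relaxation_time_s > 0:
            errs.append("relaxation_time_s: must be > 0")
        if not self.boundary_margin_m > 0:
            errs.append("boundary_margin_m: must be > 0")
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


@dataclass(frozen=True)
class MotionState:
    x_m: float
    y_m: float
    vx_m_s: float = 0.0
    vy_m_s: float = 0.0


@dataclass(frozen=True)
class GroundTruthRecord:
    frame_index: int
    time_s: float
    marker_x_m: float
    marker_y_m: float
    marker_u_px: float
    marker_v_px: float
    occluded: bool


def initial_state(scene: SceneConfig) -> MotionState:
    """Animal at the arena centre, at rest."""
    return MotionState(scene.arena_width_m / 2, scene.arena_height_m / 2)


def _reflect(p: float, v: float, lo: float, hi: float) -> tuple[float, float]:
    # fold back into [lo, hi], flipping velocity once per bounce
    for _ in range(64):
        if p < lo:
            p, v = 2 * lo - p, -v
        elif p > hi:
            p, v = 2 * hi - p, -v
        else:
            return p, v
    raise OutOfArenaError("position diverged during reflection")


def step_motion(
    state: MotionState,
    params: MotionParams,
    dt: float,
    rng: np.random.Generator,
    arena_size_m: tuple[float, float] = (0.20, 0.20),
) -> MotionState:
    """Advance the animal by one time step.

    Exact Ornstein-Uhlenbeck discretisation of the velocity
    (``v' = a v + s sqrt(1 - a^2) xi`` with ``a = exp(-dt / tau)``),
    Euler position update, and reflective walls.  Deterministic for a
    given generator state.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    w, h = arena_size_m
    m = params.boundary_margin_m
    if 2 * m >= min(w, h):
        raise ValueError("boundary margin leaves no room to move")
    if not (m <= state.x_m <= w - m and m <= state.y_m <= h - m):
        raise OutOfArenaError(f"state ({state.x_m}, {state.y_m}) outside arena interior")

    a = math.exp(-dt / params.relaxation_time_s)
    s = params.speed_scale_m_per_s * math.sqrt(1.0 - a * a)
    xi = rng.standard_normal(2)
    vx = a * state.vx_m_s + s * xi[0]
    vy = a * state.vy_m_s + s * xi[1]
    x, vx = _reflect(state.x_m + vx * dt, vx, m, w - m)
    y, vy = _reflect(state.y_m + vy * dt, vy, m, h - m)
    return MotionState(x, y, vx, vy)


def _fill_ellipse(
    frame: np.ndarray, cu: float, cv: float, a: float, b: float, theta: float, gray: int
) -> None:
    H, W = frame.shape[:2]
    r = max(a, b)
    u0, u1 = max(0, int(math.floor(cu - r))), min(W - 1, int(math.ceil(cu + r)))
    v0, v1 = max(0, int(math.floor(cv - r))), min(H - 1, int(math.ceil(cv + r)))
    if u0 > u1 or v0 > v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
    du, dv = uu - cu, vv - cv
    ct, st = math.cos(theta), math.sin(theta)
    p = du * ct + dv * st
    q = -du * st + dv * ct
    inside = (p / a) ** 2 + (q / b) ** 2 <= 1.0
    frame[v0 : v1 + 1, u0 : u1 + 1][inside] = gray


def _fill_disk(frame: np.ndarray, cu: float, cv: float, r: float, rgb) -> None:
    H, W = frame.shape[:2]
    u0, u1 = max(0, int(math.floor(cu - r))), min(W - 1, int(math.ceil(cu + r)))
    v0, v1 = max(0, int(math.floor(cv - r))), min(H - 1, int(math.ceil(cv + r)))
    if u0 > u1 or v0 > v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
    inside = (uu - cu) ** 2 + (vv - cv) ** 2 <= r * r
    frame[v0 : v1 + 1, u0 : u1 + 1][inside] = rgb


def render_frame(
    scene: SceneConfig,
    marker_pos_m: tuple[float, float],
    occluded: bool = False,
    *,
    heading_rad: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    frame_index: int = 0,
    time_s: float = 0.0,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render one 8-bit RGB frame and its ground-truth record.

    Draws, in order: uniform background, body ellipse centred on the marker
    (major axis along ``heading_rad``), the marker disk (skipped while
    occluded), then Gaussian sensor noise clipped to [0, 255].  Pixel
    membership uses pixel-centre-in-shape tests, so the rendered marker is
    exactly the set of integer pixel centres within ``marker_radius_px`` of
    the marker's sub-pixel projection.
    """
    x, y = marker_pos_m
    if not (0 <= x <= scene.arena_width_m and 0 <= y <= scene.arena_height_m):
        raise OutOfArenaError(f"marker position ({x}, {y}) outside arena")

    H, W = scene.image_height_px, scene.image_width_px
    frame = np.full((H, W, 3), scene.background_gray, dtype=np.uint8)
    cu, cv = scene.arena_to_pixel(x, y)

    a, b = scene.body_axes_px
    _fill_ellipse(frame, cu, cv, a, b, heading_rad, scene.body_gray)
    if not occluded:
        _fill_disk(frame, cu, cv, scene.marker_radius_px, scene.marker_rgb)

    if scene.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(scene.seed)
        noisy = frame + rng.normal(0.0, scene.noise_sigma, frame.shape)
        frame = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    gt = GroundTruthRecord(
        frame_index=frame_index,
        time_s=time_s,
        marker_x_m=x,
        marker_y_m=y,
        marker_u_px=cu,
        marker_v_px=cv,
        occluded=occluded,
    )
    return frame, gt


def add_salt_pepper(
    frame: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt a fraction of pixels to pure black or pure white (50/50)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    out = frame.copy()
    H, W = frame.shape[:2]
    n = int(round(fraction * H * W))
    if n == 0:
        return out
    idx = rng.choice(H * W, size=n, replace=False)
    salt = rng.random(n) < 0.5
    vv, uu = np.unravel_index(idx, (H, W))
    out[vv[salt], uu[salt]] = 255
    out[vv[~salt], uu[~salt]] = 0
    return out


def iter_scene(
    scene: SceneConfig, motion: MotionParams
) -> Iterator[tuple[np.ndarray, GroundTruthRecord]]:
    """Yield ``(frame, ground_truth)`` for each frame of the configured scene.

    One seeded generator drives both the motion and the sensor noise, so a
    given ``(scene, motion)`` pair always produces an identical sequence.
    The body ellipse is oriented along the instantaneous velocity.
    """
    rng = np.random.default_rng(scene.seed)
    state = initial_state(scene)
    arena = (scene.arena_width_m, scene.arena_height_m)
    dt = 1.0 / scene.fps
    for k in range(scene.n_frames):
        if k > 0:
            state = step_motion(state, motion, dt, rng, arena)
        speed = math.hypot(state.vx_m_s, state.vy_m_s)
        heading = math.atan2(state.vy_m_s, state.vx_m_s) if speed > 0 else 0.0
        yield render_frame(
            scene,
            (state.x_m, state.y_m),
            occluded=scene.is_occluded(k),
            heading_rad=heading,
            rng=rng,
            frame_index=k,
            time_s=k * dt,
        )


def ground_truth_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=GROUND_TRUTH_COLUMNS)


def generate_dataset(
    scene: SceneConfig, motion: MotionParams, out_dir: str | Path
) -> pd.DataFrame:
    """Write the scene to disk: ``frame_%06d.png`` files plus ``ground_truth.csv``.

    Returns the ground-truth table.  Fully reproducible from the scene seed;
    the CSV is written atomically and is byte-identical across runs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out}: {e}") from e
    records = []
    for frame, gt in iter_scene(scene, motion):
        atomic_write_bytes(
            out / f"frame_{gt.frame_index:06d}.png",
            iio.imwrite("<bytes>", frame, extension=".png"),
        )
        records.append(gt)
    df = ground_truth_frame(records)
    from .files import atomic_write_text

    atomic_write_text(out / "ground_truth.csv", df.to_csv(index=False))
    return df
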