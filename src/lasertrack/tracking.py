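"""Colour-mask marker tracking.

The vision pipeline mirrors the workflow of the overhead-camera rig:

1. a colour mask flags pixels whose colour matches the pen mark;
2. morphological opening (erosion then dilation, disk element) removes
   speckle from sensor noise;
3. connected components are extracted and each blob's centroid is the
   arithmetic mean of its member pixel coordinates, computed frame by frame.

On top of that sit the parts any practical tracker needs but which are
policy choices: blob selection (size gate, proximity to the previous fix),
exponential smoothing of the centroid, and a hold-then-drop rule for frames
where the marker is not seen (occlusion, grooming).

Red pen marks are detected in HSV by default, with two hue windows to cover
the red wrap-around at 0/360 degrees.  Hue is in degrees [0, 360); saturation
and value in [0, 1]; RGB bounds are 0-255.  All bounds are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .files import atomic_write_text

__all__ = [
    "ColorSpec",
    "TrackerParams",
    "Blob",
    "TrackState",
    "default_red_spec",
    "rgb_to_hsv_deg",
    "color_mask",
    "morphological_clean",
    "extract_blobs",
    "select_target",
    "update_track",
    "track_sequence",
    "tracks_to_dataframe",
    "write_trajectory",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = [
    "frame_index",
    "time_s",
    "found",
    "raw_u_px",
    "raw_v_px",
    "smooth_u_px",
    "smooth_v_px",
    "hold_counter",
]

Window = tuple[tuple[float, float, float], tuple[float, float, float]]


@dataclass(frozen=True)
class ColorSpec:
    """Per-channel colour bounds defining mask foreground.

    ``windows`` is a sequence of ``(lower, upper)`` channel-bound pairs; a
    pixel is foreground if it falls inside any window (bounds inclusive).
    Two windows allow the hue wrap-around of red in HSV.
    """

    space: str = "hsv"
    windows: tuple[Window, ...] = ()

    def validate(self) -> list[str]:
        errs = []
        if self.space not in ("rgb", "hsv"):
            errs.append(f"space: must be 'rgb' or 'hsv', got {self.space!r}")
        if len(self.windows) == 0:
            errs.append("windows: at least one colour window required")
        for i, (lo, hi) in enumerate(self.windows):
            if len(lo) != 3 or len(hi) != 3:
                errs.append(f"windows[{i}]: bounds must have 3 channels")
            elif any(l > h for l, h in zip(lo, hi)):
                errs.append(f"windows[{i}]: lower bound exceeds upper bound")
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


def default_red_spec() -> ColorSpec:
    """HSV spec for a red pen mark: hue within 15 deg of 0/360, saturated, bright."""
    return ColorSpec(
        space="hsv",
        windows=(
            ((0.0, 0.40, 0.20), (15.0, 1.0, 1.0)),
            ((345.0, 0.40, 0.20), (360.0, 1.0, 1.0)),
        ),
    )


@dataclass(frozen=True)
class TrackerParams:
    """Pipeline knobs: cleanup size, blob gates, smoothing, and loss handling.

    ``hold_frames`` keeps reporting the last smoothed position for that many
    frames after the marker disappears before declaring the target lost;
    ``max_jump_px`` rejects blobs implausibly far from the previous fix in a
    single frame.
    """

    opening_radius_px: int = 2
    min_blob_px: int = 20
    max_jump_px: float = 80.0
    ema_alpha: float = 0.5
    hold_frames: int = 15

    def validate(self) -> list[str]:
        errs = []
        if self.opening_radius_px < 0:
            errs.append("opening_radius_px: must be >= 0")
        if self.min_blob_px < 0:
            errs.append("min_blob_px: must be >= 0")
        if self.max_jump_px <= 0:
            errs.append("max_jump_px: must be > 0")
        if not 0 < self.ema_alpha <= 1:
            errs.append("ema_alpha: must be in (0, 1]")
        if self.hold_frames < 0:
            errs.append("hold_frames: must be >= 0")
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


@dataclass(frozen=True)
class Blob:
    """A connected foreground component (8-connectivity)."""

    pixel_count: int
    centroid_u: float
    centroid_v: float
    bbox: tuple[int, int, int, int]  # (u_min, v_min, u_max, v_max) inclusive


@dataclass(frozen=True)
class TrackState:
    """Per-frame tracker output.

    ``raw_centroid`` is the selected blob's centroid for this frame (absent
    when nothing was detected); ``smoothed_centroid`` is the exponentially
    smoothed estimate, retained through short detection gaps and dropped
    once ``hold_counter`` exceeds the hold budget.
    """

    frame_index: int
    raw_centroid: Optional[tuple[float, float]] = None
    smoothed_centroid: Optional[tuple[float, float]] = None
    found: bool = False
    hold_counter: int = 0


def rgb_to_hsv_deg(frame: np.ndarray) -> np.ndarray:
    """Hexagonal HSV conversion of an 8-bit RGB image.

    Returns float64 with hue in degrees [0, 360), saturation and value in
    [0, 1].  With chroma ``c = max - min``: ``h = 60 (g - b) / c mod 360``
    when red is the maximum channel, ``60 (b - r) / c + 120`` when green,
    ``60 (r - g) / c + 240`` when blue (ties resolved in that order);
    ``s = c / max`` (0 for black); ``v = max / 255``.
    """
    f = np.asarray(frame, dtype=np.float64)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    c = mx - np.minimum(np.minimum(r, g), b)
    h = np.zeros_like(mx)
    nz = c > 0
    rm = nz & (r == mx)
    gm = nz & ~rm & (g == mx)
    bm = nz & ~rm & ~gm
    h[rm] = (60.0 * (g[rm] - b[rm]) / c[rm]) % 360.0
    h[gm] = 60.0 * (b[gm] - r[gm]) / c[gm] + 120.0
    h[bm] = 60.0 * (r[bm] - g[bm]) / c[bm] + 240.0
    s = np.zeros_like(mx)
    pos = mx > 0
    s[pos] = c[pos] / mx[pos]
    return np.stack([h, s, mx / 255.0], axis=-1)


def color_mask(frame: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Boolean mask of pixels whose colour lies inside the spec's bounds.

    A pure per-pixel function: RGB frames are compared directly against the
    0-255 bounds; for HSV specs the frame is converted first via
    :func:`rgb_to_hsv_deg`.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3 or frame.dtype != np.uint8:
        raise ValueError(f"expected 8-bit RGB frame (H, W, 3) uint8, got {frame.dtype} {frame.shape}")
    if spec.space == "hsv":
        img = rgb_to_hsv_deg(frame)
    else:
        img = frame.astype(float)
    mask = np.zeros(frame.shape[:2], dtype=bool)
    for lo, hi in spec.windows:
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        mask |= ((img >= lo) & (img <= hi)).all(axis=2)
    return mask


def morphological_clean(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a disk structuring element.

    Erosion then dilation with the same disk; removes foreground components
    the disk cannot fit inside while leaving larger shapes intact.  Pixels
    beyond the image border count as background.  Radius 0 is the identity.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    return ndimage.binary_opening(mask, structure=disk(radius).astype(bool))


def extract_blobs(mask: np.ndarray) -> list[Blob]:
    """Connected components of the mask, 8-connected.

    Each blob's centroid is the arithmetic mean of its member pixel
    coordinates.  Blobs are sorted by pixel count descending, ties broken by
    (centroid_v, centroid_u) ascending so the ordering is total and
    reproducible.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    blobs = []
    for i in range(1, n + 1):
        vv, uu = np.nonzero(labels == i)
        blobs.append(
            Blob(
                pixel_count=len(uu),
                centroid_u=float(uu.mean()),
                centroid_v=float(vv.mean()),
                bbox=(int(uu.min()), int(vv.min()), int(uu.max()), int(vv.max())),
            )
        )
    blobs.sort(key=lambda b: (-b.pixel_count, b.centroid_v, b.centroid_u))
    return blobs


def _prev_centroid(prev: Optional[TrackState]) -> Optional[tuple[float, float]]:
    if prev is None:
        return None
    return prev.smoothed_centroid or prev.raw_centroid


def select_target(
    blobs: Sequence[Blob], prev: Optional[TrackState], params: TrackerParams
) -> Optional[Blob]:
    """Pick the blob to track this frame.

    Blobs below ``min_blob_px`` are discarded.  With a previous fix, the
    nearest surviving blob within ``max_jump_px`` wins; otherwise (or when
    none is near enough) the largest surviving blob wins.  Returns ``None``
    when nothing survives.
    """
    survivors = [b for b in blobs if b.pixel_count >= params.min_blob_px]
    if not survivors:
        return None
    anchor = _prev_centroid(prev)
    if anchor is not None:
        au, av = anchor
        near = [
            b
            for b in survivors
            if math.hypot(b.centroid_u - au, b.centroid_v - av) <= params.max_jump_px
        ]
        if near:
            return min(
                near,
                key=lambda b: (
                    math.hypot(b.centroid_u - au, b.centroid_v - av),
                    -b.pixel_count,
                    b.centroid_v,
                    b.centroid_u,
                ),
            )
    return min(survivors, key=lambda b: (-b.pixel_count, b.centroid_v, b.centroid_u))


def update_track(
    prev: Optional[TrackState], selection: Optional[Blob], params: TrackerParams,
    frame_index: Optional[int] = None,
) -> TrackState:
    """Fold one frame's selection into the track state.

    On detection the smoothed centroid is the exponential moving average
    ``alpha * raw + (1 - alpha) * previous`` (or the raw centroid on the
    first detection) and the hold counter resets.  On a miss the counter
    increments and the last smoothed position is held for ``hold_frames``
    frames, after which the target is reported absent.
    """
    if frame_index is None:
        frame_index = prev.frame_index + 1 if prev is not None else 0
    if selection is not None:
        raw = (selection.centroid_u, selection.centroid_v)
        prev_smooth = prev.smoothed_centroid if prev is not None else None
        if prev_smooth is None:
            smooth = raw
        else:
            a = params.ema_alpha
            smooth = (
                a * raw[0] + (1 - a) * prev_smooth[0],
                a * raw[1] + (1 - a) * prev_smooth[1],
            )
        return TrackState(frame_index, raw, smooth, found=True, hold_counter=0)
    hold = (prev.hold_counter + 1) if prev is not None else 1
    smooth = prev.smoothed_centroid if (prev is not None and hold <= params.hold_frames) else None
    return TrackState(frame_index, None, smooth, found=False, hold_counter=hold)


def _frame_source(frames) -> Iterable[np.ndarray]:
    if isinstance(frames, (str, Path)):
        d = Path(frames)
        paths = sorted(d.glob("*.png")) + sorted(d.glob("*.tif")) + sorted(d.glob("*.tiff"))
        if not paths:
            raise IOError(f"no PNG/TIFF frames found in {d}")
        import imageio.v3 as iio

        def gen():
            for p in paths:
                yield iio.imread(p)

        return gen()
    return frames


def track_sequence(
    frames, spec: ColorSpec, params: TrackerParams
) -> list[TrackState]:
    """Run the full pipeline over a frame sequence.

    ``frames`` may be a directory of PNG/TIFF files (sorted by name) or any
    iterable of 8-bit RGB arrays.  Returns one :class:`TrackState` per frame.
    """
    states: list[TrackState] = []
    prev: Optional[TrackState] = None
    for k, frame in enumerate(_frame_source(frames)):
        try:
            mask = color_mask(np.asarray(frame), spec)
        except ValueError as e:
            raise IOError(f"frame {k}: {e}") from e
        mask = morphological_clean(mask, params.opening_radius_px)
        blobs = extract_blobs(mask)
        sel = select_target(blobs, prev, params)
        prev = update_track(prev, sel, params, frame_index=k)
        states.append(prev)
    if not states:
        raise ValueError("empty frame source")
    return states


def tracks_to_dataframe(states: Sequence[TrackState], fps: float) -> pd.DataFrame:
    rows = []
    for s in states:
        rows.append(
            {
                "frame_index": s.frame_index,
                "time_s": s.frame_index / fps,
                "found": s.found,
                "raw_u_px": s.raw_centroid[0] if s.raw_centroid else np.nan,
                "raw_v_px": s.raw_centroid[1] if s.raw_centroid else np.nan,
                "smooth_u_px": s.smoothed_centroid[0] if s.smoothed_centroid else np.nan,
                "smooth_v_px": s.smoothed_centroid[1] if s.smoothed_centroid else np.nan,
                "hold_counter": s.hold_counter,
            }
        )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectory(states: Sequence[TrackState], fps: float, path) -> None:
    atomic_write_text(path, tracks_to_dataframe(states, fps).to_csv(index=False))
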