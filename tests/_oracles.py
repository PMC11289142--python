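"""Independent brute-force oracles used to check the vectorised pipeline.

Everything here is deliberately slow and simple: per-pixel Python loops,
explicit sliding windows, breadth-first flood fill, and explicit 3-D
ray/plane intersection.  None of it shares code with the implementation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def hsv_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Scalar hexagonal HSV of one 8-bit RGB pixel (h degrees, s/v in [0,1])."""
    mx = max(r, g, b)
    mn = min(r, g, b)
    c = mx - mn
    if c == 0:
        h = 0.0
    elif mx == r:
        h = (60.0 * (g - b) / c) % 360.0
    elif mx == g:
        h = 60.0 * (b - r) / c + 120.0
    else:
        h = 60.0 * (r - g) / c + 240.0
    s = c / mx if mx > 0 else 0.0
    return h, s, mx / 255.0


def mask_oracle(frame: np.ndarray, spec) -> np.ndarray:
    """Per-pixel bound check duplicating the ColorSpec contract."""
    H, W = frame.shape[:2]
    out = np.zeros((H, W), dtype=bool)
    for v in range(H):
        for u in range(W):
            r, g, b = (int(frame[v, u, k]) for k in range(3))
            px = hsv_pixel(r, g, b) if spec.space == "hsv" else (float(r), float(g), float(b))
            for lo, hi in spec.windows:
                if all(lo[k] <= px[k] <= hi[k] for k in range(3)):
                    out[v, u] = True
                    break
    return out


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dv, du)
        for dv in range(-radius, radius + 1)
        for du in range(-radius, radius + 1)
        if dv * dv + du * du <= radius * radius
    ]


def opening_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    """Min-then-max sliding window with a disk element; out of bounds is background."""
    offs = disk_offsets(radius)
    H, W = mask.shape

    def erode(m):
        out = np.zeros_like(m)
        for v in range(H):
            for u in range(W):
                out[v, u] = all(
                    0 <= v + dv < H and 0 <= u + du < W and m[v + dv, u + du]
                    for dv, du in offs
                )
        return out

    def dilate(m):
        out = np.zeros_like(m)
        for v in range(H):
            for u in range(W):
                out[v, u] = any(
                    0 <= v + dv < H and 0 <= u + du < W and m[v + dv, u + du]
                    for dv, du in offs
                )
        return out

    return dilate(erode(np.asarray(mask, dtype=bool)))


def flood_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by breadth-first flood fill; lists of (v, u)."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for v0 in range(H):
        for u0 in range(W):
            if mask[v0, u0] and not seen[v0, u0]:
                comp = []
                q = deque([(v0, u0)])
                seen[v0, u0] = True
                while q:
                    v, u = q.popleft()
                    comp.append((v, u))
                    for dv in (-1, 0, 1):
                        for du in (-1, 0, 1):
                            vv, uu = v + dv, u + du
                            if 0 <= vv < H and 0 <= uu < W and mask[vv, uu] and not seen[vv, uu]:
                                seen[vv, uu] = True
                                q.append((vv, uu))
                comps.append(comp)
    return comps


def disk_pixel_count(cu: float, cv: float, radius: float, width: int, height: int) -> int:
    """Pixel centres inside a disk, by exhaustive scan."""
    n = 0
    for v in range(height):
        for u in range(width):
            if (u - cu) ** 2 + (v - cv) ** 2 <= radius * radius:
                n += 1
    return n


def ray_plane_spot(mount, pan_deg: float, tilt_deg: float, axis=(1.0, 0.0)):
    """Explicit 3-D ray/floor-plane intersection for the beam direction."""
    ax, ay = axis
    n = math.hypot(ax, ay)
    base = math.atan2(ay, ax)
    ang = base + math.radians(pan_deg)
    t = math.radians(tilt_deg)
    d = np.array([math.sin(t) * math.cos(ang), math.sin(t) * math.sin(ang), -math.cos(t)])
    o = np.array(mount, dtype=float)
    lam = -o[2] / d[2]
    p = o + lam * d
    return float(p[0]), float(p[1])
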