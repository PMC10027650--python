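"""Deterministic schematic avatar renderer.

Maps a face state to an 8-bit RGB raster with a pure function: the same
(avatar, state, size) triple always yields a byte-identical image.  The
avatar is a flat-shaded 2D face — head ellipse, brows, eyes, nose, mouth —
whose geometry deforms monotonically with the mapped action units:

* brows: AU01 (inner raise) / AU02 (outer raise) lift, AU04 (lowerer) drops
* eyes:  AU05 (upper-lid raise) widens, AU07 (lid tightener) narrows,
  AU45 (blink) closes
* mouth: AU12 (smile) / AU20 (stretch) widen, AU25 (lips part) / AU26
  (jaw drop) open, AU15 (corner depressor) pulls down

Yaw and pitch are rendered as horizontal/vertical shifts of the whole face,
roll rotates the feature layout, and tz scales the head — an affine stand-in
that is sufficient for calibration tracks (the yaw signal is recoverable
from the head-pixel centroid) while remaining exactly reproducible.

A pluggable contract lets an external photorealistic renderer replace this
one: any callable ``(FaceState, avatar_id, (width, height)) -> ndarray``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .face import FaceState


@dataclass(frozen=True)
class AvatarModel:
    """Appearance parameters of one schematic avatar identity."""

    avatar_id: str
    skin: tuple[int, int, int] = (224, 182, 158)
    hair: tuple[int, int, int] = (72, 48, 30)
    eye: tuple[int, int, int] = (52, 84, 120)
    mouth: tuple[int, int, int] = (168, 72, 80)
    background: tuple[int, int, int] = (40, 40, 46)
    head_width: float = 40.0   # base half-axes, in layout units
    head_height: float = 52.0


#: Four stock identities, mirroring a small pool of study avatars.
DEFAULT_AVATARS: dict[str, AvatarModel] = {
    "a1": AvatarModel("a1", skin=(224, 182, 158), hair=(72, 48, 30)),
    "a2": AvatarModel("a2", skin=(198, 152, 122), hair=(28, 24, 22), eye=(70, 52, 36)),
    "a3": AvatarModel("a3", skin=(240, 205, 180), hair=(160, 120, 60), eye=(60, 110, 70)),
    "a4": AvatarModel("a4", skin=(172, 126, 100), hair=(10, 10, 12), eye=(40, 36, 34)),
}

_registry: dict[str, AvatarModel] = dict(DEFAULT_AVATARS)


def register_avatar(model: AvatarModel) -> None:
    """Register (or replace) an avatar identity by id."""
    _registry[model.avatar_id] = model


def registered_avatar_ids() -> list[str]:
    return sorted(_registry)


def get_avatar(avatar_id: str) -> AvatarModel:
    try:
        return _registry[avatar_id]
    except KeyError:
        raise ValueError(
            f"unknown avatar id {avatar_id!r}; registered: {registered_avatar_ids()}"
        ) from None


@lru_cache(maxsize=8)
def _grid(width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:height, 0:width]
    return xx.astype(float), yy.astype(float)


def _paint_ellipse(canvas, xx, yy, cx, cy, rx, ry, color) -> None:
    if rx <= 0 or ry <= 0:
        return
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    canvas[mask] = color


def render_state(
    state: FaceState,
    avatar: AvatarModel | str = "a1",
    size: tuple[int, int] = (128, 128),
) -> np.ndarray:
    """Render a face state to an ``(H, W, 3)`` uint8 raster.

    Pure and deterministic.  An invalid state renders the neutral face with
    a red "tracking lost" border.
    """
    if isinstance(avatar, str):
        avatar = get_avatar(avatar)
    width, height = size
    if width < 64 or height < 64:
        raise ValueError("image size must be at least 64x64")

    invalid = not state.valid
    if invalid:
        state = FaceState.neutral()

    au = state.expression
    pose = state.pose
    u = min(width, height) / 128.0  # layout unit

    # Affine pose mapping: yaw/pitch shift, tz scales, roll rotates features.
    scale = float(np.clip(1.0 - pose.tz / 2000.0, 0.5, 1.5))
    cx = width / 2.0 + (0.4 * pose.tx + 0.9 * pose.ry) * u
    cy = height / 2.0 + (-0.4 * pose.ty + 0.9 * pose.rx) * u
    roll = math.radians(pose.rz)
    cos_r, sin_r = math.cos(roll), math.sin(roll)

    def place(dx: float, dy: float) -> tuple[float, float]:
        dx, dy = dx * scale * u, dy * scale * u
        return cx + dx * cos_r - dy * sin_r, cy + dx * sin_r + dy * cos_r

    canvas = np.empty((height, width, 3), dtype=np.uint8)
    canvas[:] = avatar.background
    xx, yy = _grid(width, height)

    # Head: ellipse, slightly narrowed when turned (foreshortening cue).
    head_rx = avatar.head_width * scale * u * (1.0 - 0.004 * abs(pose.ry))
    head_ry = avatar.head_height * scale * u
    _paint_ellipse(canvas, xx, yy, cx, cy, head_rx, head_ry, avatar.skin)

    # Brows: AU01/AU02 raise (inner/outer, averaged into one bar here),
    # AU04 lowers.
    brow_lift = (0.8 * au["AU01"] + 1.2 * au["AU02"] - 1.2 * au["AU04"])
    for side in (-1, 1):
        bx, by = place(side * 20.0, -30.0 - brow_lift)
        _paint_ellipse(canvas, xx, yy, bx, by, 11.0 * scale * u, 2.2 * scale * u, avatar.hair)

    # Eyes: openness grows with AU05, shrinks with AU07, collapses with AU45.
    eye_ry = 4.5 * (1.0 + 0.12 * au["AU05"]) * (1.0 - 0.08 * au["AU07"])
    eye_ry *= max(0.0, 1.0 - 0.95 * au["AU45"] / 5.0)
    for side in (-1, 1):
        ex, ey = place(side * 20.0, -14.0)
        _paint_ellipse(canvas, xx, yy, ex, ey, 9.0 * scale * u,
                       max(eye_ry, 0.4) * scale * u, (245, 245, 245))
        _paint_ellipse(canvas, xx, yy, ex, ey, 3.2 * scale * u,
                       max(eye_ry * 0.75, 0.3) * scale * u, avatar.eye)

    # Nose: static.
    nx, ny = place(0.0, 6.0)
    _paint_ellipse(canvas, xx, yy, nx, ny, 4.0 * scale * u, 7.0 * scale * u,
                   tuple(int(c * 0.88) for c in avatar.skin))

    # Mouth: width from AU12/AU20/AU14, opening from AU25/AU26, vertical
    # shift from AU15 (down) and AU17 (up).
    mouth_drop = 0.8 * au["AU15"] - 0.5 * au["AU17"]
    mx, my = place(0.0, 30.0 + mouth_drop)
    mouth_rx = (13.0 + 1.4 * au["AU12"] + 0.9 * au["AU20"] + 0.3 * au["AU14"])
    mouth_ry = (2.6 + 1.4 * au["AU25"] + 2.2 * au["AU26"])
    _paint_ellipse(canvas, xx, yy, mx, my, mouth_rx * scale * u,
                   mouth_ry * scale * u, avatar.mouth)
    if mouth_ry > 5.0:  # visible mouth interior once clearly open
        _paint_ellipse(canvas, xx, yy, mx, my, mouth_rx * 0.7 * scale * u,
                       (mouth_ry - 2.0) * scale * u, (40, 20, 24))

    if invalid:
        b = max(2, int(3 * u))
        canvas[:b, :] = (200, 30, 30)
        canvas[-b:, :] = (200, 30, 30)
        canvas[:, :b] = (200, 30, 30)
        canvas[:, -b:] = (200, 30, 30)
    return canvas


def head_mask(image: np.ndarray, background: tuple[int, int, int] = (40, 40, 46)) -> np.ndarray:
    """Binary mask of non-background pixels (used by centroid oracles)."""
    return np.any(image != np.asarray(background, dtype=np.uint8), axis=-1)


def save_png(image: np.ndarray, path: str | Path) -> None:
    """Write a raster as PNG."""
    from PIL import Image

    Image.fromarray(image).save(str(path), format="PNG")
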