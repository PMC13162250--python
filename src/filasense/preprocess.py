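"""Frame cropping, resizing, and the training augmentation policy.

Coordinates are 0-based, half-open pixel indices throughout.  Resizing uses
bilinear interpolation with the center-aligned convention (output pixel ``i``
samples input coordinate ``(i + 0.5) * in/out - 0.5``, edges clamped) plus a
Gaussian anti-alias prefilter when downscaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentPolicy", "AugmentParams", "crop_segments", "resize_image",
           "sample_augment_params", "augment"]

FRAME_SHAPE = (1200, 1920)
SEGMENT_SIDE = 960
_BAND_TOP = (FRAME_SHAPE[0] - SEGMENT_SIDE) // 2  # 120


def crop_segments(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 1920x1200 frame into two 960x960 segments.

    Both segments take rows [120, 1080) — vertically centred so the filament
    stripe survives — with the left segment columns [0, 960) and the right
    [960, 1920).
    """
    if frame.shape[:2] != FRAME_SHAPE:
        raise ValueError(f"expected a {FRAME_SHAPE[1]}x{FRAME_SHAPE[0]} frame, "
                         f"got shape {frame.shape}")
    r0, r1 = _BAND_TOP, _BAND_TOP + SEGMENT_SIDE
    return (np.ascontiguousarray(frame[r0:r1, 0:SEGMENT_SIDE]),
            np.ascontiguousarray(frame[r0:r1, SEGMENT_SIDE:2 * SEGMENT_SIDE]))


def _axis_weights(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    pos = np.clip(pos, 0.0, n_in - 1.0)
    i0 = np.floor(pos).astype(int)
    i0 = np.minimum(i0, n_in - 2) if n_in > 1 else i0
    frac = pos - i0
    return i0, i0 + 1, frac


def resize_image(image: np.ndarray, side: int, anti_alias: bool = True) -> np.ndarray:
    """Bilinear resize to side x side (float32 output, value range preserved).

    When downscaling with ``anti_alias``, a Gaussian prefilter of sigma
    ``(ratio - 1) / 2`` per axis suppresses aliasing of structures narrower
    than the output sampling step.
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    img = np.asarray(image, dtype=np.float32)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    h, w = img.shape[:2]
    if anti_alias:
        sig = [max(0.0, (h / side - 1.0) / 2.0), max(0.0, (w / side - 1.0) / 2.0), 0.0]
        if max(sig) > 0:
            img = ndimage.gaussian_filter(img, sigma=sig, mode="nearest")
    r0, r1, rf = _axis_weights(h, side)
    c0, c1, cf = _axis_weights(w, side)
    rows = img[r0] * (1.0 - rf)[:, None, None] + img[r1] * rf[:, None, None]
    out = (rows[:, c0] * (1.0 - cf)[None, :, None]
           + rows[:, c1] * cf[None, :, None]).astype(np.float32)
    return out[:, :, 0] if squeeze else out


@dataclass(frozen=True)
class AugmentPolicy:
    """Training-time augmentation ranges.

    Vertical translation is bounded by one-eighth of the input height;
    horizontal translation is disabled (a large x-shift could push emission
    events out of the frame).
    """

    reflect_x: bool = True
    reflect_y: bool = True
    rotation_deg: float = 5.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    translate_frac: float = 1.0 / 8.0

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(reflect_x=False, reflect_y=False, rotation_deg=0.0,
                   scale_range=(1.0, 1.0), translate_frac=0.0)


@dataclass(frozen=True)
class AugmentParams:
    flip_x: bool
    flip_y: bool
    rotation_deg: float
    scale_x: float
    scale_y: float
    translate_y: float
    translate_x: float = 0.0   # always zero by policy


def sample_augment_params(policy: AugmentPolicy, rng: np.random.Generator,
                          height: int) -> AugmentParams:
    """One random draw of every enabled transform."""
    lo, hi = policy.scale_range
    return AugmentParams(
        flip_x=bool(policy.reflect_x and rng.random() < 0.5),
        flip_y=bool(policy.reflect_y and rng.random() < 0.5),
        rotation_deg=float(rng.uniform(-policy.rotation_deg, policy.rotation_deg)),
        scale_x=float(rng.uniform(lo, hi)),
        scale_y=float(rng.uniform(lo, hi)),
        translate_y=float(rng.uniform(-policy.translate_frac * height,
                                      policy.translate_frac * height)),
    )


def _affine_matrix(params: AugmentParams, h: int, w: int) -> np.ndarray:
    """Forward (x, y, 1) homogeneous matrix: reflect, rotate, scale about the
    image centre, then translate vertically."""
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    t = np.deg2rad(params.rotation_deg)

    def mat(a, b, c, d, tx=0.0, ty=0.0):
        return np.array([[a, b, tx], [c, d, ty], [0.0, 0.0, 1.0]])

    center = mat(1, 0, 0, 1, -cx, -cy)
    reflect = mat(-1.0 if params.flip_x else 1.0, 0, 0,
                  -1.0 if params.flip_y else 1.0)
    rotate = mat(np.cos(t), -np.sin(t), np.sin(t), np.cos(t))
    scale = mat(params.scale_x, 0, 0, params.scale_y)
    uncenter = mat(1, 0, 0, 1, cx, cy)
    translate = mat(1, 0, 0, 1, params.translate_x, params.translate_y)
    return translate @ uncenter @ scale @ rotate @ reflect @ center


def augment(image: np.ndarray, policy: AugmentPolicy | None = None,
            seed: int | None = None,
            params: AugmentParams | None = None) -> np.ndarray:
    """Apply one random draw of the augmentation policy (reflect, rotate,
    scale, vertical translate, in that order) with reflect border fill.

    Pass ``params`` to replay a specific draw.  Deterministic under a fixed
    seed; square input required.
    """
    from skimage.transform import warp

    img = np.asarray(image)
    if img.shape[0] != img.shape[1]:
        raise ValueError("augment expects a square image")
    if params is None:
        policy = policy or AugmentPolicy()
        rng = np.random.default_rng(seed)
        params = sample_augment_params(policy, rng, img.shape[0])
    fwd = _affine_matrix(params, img.shape[0], img.shape[1])
    if np.allclose(fwd, np.eye(3)):
        return img.astype(np.float32, copy=True)
    out = warp(img, np.linalg.inv(fwd), order=1, mode="reflect",
               preserve_range=True)
    return out.astype(np.float32)
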