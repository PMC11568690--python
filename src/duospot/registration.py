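"""Rigid-body registration of background scans and background subtraction.

The background scan (re-imaged after stripping in situ signals) is slightly
misaligned with the original scan.  Alignment is estimated on binned nuclear
images, the translation is upscaled to full resolution, refined per ROI, and
the registered background is subtracted from every signal channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "RigidTransform",
    "SamplePair",
    "bin_image",
    "estimate_rigid",
    "scale_transform",
    "apply_rigid",
    "subtract_background",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the image center followed by a translation.

    Forward map on (row, col) points::

        p' = R(theta) @ (p - center) + center + (dy, dx)

    ``theta`` is in degrees, counter-clockwise in (row, col) axes.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.dx, self.dy, self.theta])):
            raise ValueError("transform parameters must be finite")

    @property
    def rotation_matrix(self) -> np.ndarray:
        t = np.deg2rad(self.theta)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def inverse(self) -> "RigidTransform":
        rinv = RigidTransform(theta=-self.theta).rotation_matrix
        dy, dx = -rinv @ np.array([self.dy, self.dx])
        return RigidTransform(dx=float(dx), dy=float(dy), theta=-self.theta)

    def apply_points(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Forward-map an (n, 2) array of (row, col) points."""
        center = (np.asarray(shape, float) - 1.0) / 2.0
        pts = np.atleast_2d(np.asarray(points, float))
        out = (self.rotation_matrix @ (pts - center).T).T + center
        return out + np.array([self.dy, self.dx])

    def to_json(self) -> str:
        return json.dumps({"dx": self.dx, "dy": self.dy, "theta": self.theta})

    @classmethod
    def from_json(cls, data: str) -> "RigidTransform":
        d = json.loads(data)
        return cls(dx=d["dx"], dy=d["dy"], theta=d["theta"])


@dataclass
class SamplePair:
    """Matched original and background scans as channel -> 2D image maps."""

    original: dict[str, np.ndarray]
    background: dict[str, np.ndarray]
    validity_mask: np.ndarray | None = None
    transform: RigidTransform | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scan in (self.original, self.background):
            shapes = {img.shape for img in scan.values()}
            if len(shapes) > 1:
                raise ValueError(f"channels of one scan must share a shape, got {shapes}")


def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Mean-bin by ``factor`` in both axes, cropping any remainder rows/cols."""
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return np.asarray(image, float)
    h, w = image.shape
    h2, w2 = (h // factor) * factor, (w // factor) * factor
    cropped = np.asarray(image[:h2, :w2], float)
    return cropped.reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))


def apply_rigid(image: np.ndarray, t: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    """Apply a rigid transform with bilinear interpolation.

    Returns the transformed image and a validity mask that is False wherever
    the output sampled outside the source image (border voids).
    """
    img = np.asarray(image, float)
    center = (np.asarray(img.shape, float) - 1.0) / 2.0
    shift = np.array([t.dy, t.dx])
    rinv = RigidTransform(theta=-t.theta).rotation_matrix
    # output[o] = input[rinv @ (o - center - shift) + center]
    offset = center - rinv @ (center + shift)
    out = ndi.affine_transform(img, rinv, offset=offset, order=1, mode="constant", cval=0.0)
    coverage = ndi.affine_transform(
        np.ones_like(img), rinv, offset=offset, order=1, mode="constant", cval=0.0
    )
    return out, coverage > 0.999


def scale_transform(t: RigidTransform, factor: int) -> RigidTransform:
    """Upscale a transform estimated on binned images to full resolution.

    Only the translation scales with resolution; the rotation angle is
    scale-invariant.
    """
    if factor < 1:
        raise ValueError("scale factor must be >= 1")
    return RigidTransform(dx=t.dx * factor, dy=t.dy * factor, theta=t.theta)


def _mse(reference: np.ndarray, moved: np.ndarray, valid: np.ndarray) -> float:
    if valid.sum() < 16:
        return np.inf
    diff = reference[valid] - moved[valid]
    return float(np.mean(diff * diff))


def _best_shift_for_angle(
    reference: np.ndarray, moving: np.ndarray, theta: float, upsample: int
) -> tuple[RigidTransform, float]:
    rotated, _ = apply_rigid(moving, RigidTransform(theta=theta))
    shift, _, _ = phase_cross_correlation(
        reference, rotated, upsample_factor=upsample, normalization=None
    )
    t = RigidTransform(dx=float(shift[1]), dy=float(shift[0]), theta=theta)
    moved, valid = apply_rigid(moving, t)
    return t, _mse(reference, moved, valid)


def estimate_rigid(
    reference: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 5.0,
    coarse_step: float = 0.5,
    angle_tol: float = 0.02,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Translation comes from subpixel phase correlation; rotation from a coarse
    grid over ``[-max_rotation, max_rotation]`` degrees followed by a local
    parabolic refinement of the mean-squared-error objective.
    """
    reference = np.asarray(reference, float)
    moving = np.asarray(moving, float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving images must share a shape")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("degenerate input: constant image cannot be registered")

    ref = reference - reference.mean()
    mov = moving - moving.mean()

    angles = np.arange(-max_rotation, max_rotation + coarse_step / 2, coarse_step)
    best_t, best_err = None, np.inf
    for theta in angles:
        t, err = _best_shift_for_angle(ref, mov, float(theta), upsample=10)
        if err < best_err:
            best_t, best_err = t, err

    # local refinement of theta around the coarse optimum
    lo, hi = best_t.theta - coarse_step, best_t.theta + coarse_step
    for _ in range(12):
        mid1 = lo + (hi - lo) / 3
        mid2 = hi - (hi - lo) / 3
        _, e1 = _best_shift_for_angle(ref, mov, mid1, upsample=20)
        _, e2 = _best_shift_for_angle(ref, mov, mid2, upsample=20)
        if e1 <= e2:
            hi = mid2
        else:
            lo = mid1
        if hi - lo < angle_tol:
            break
    theta = (lo + hi) / 2
    final, final_err = _best_shift_for_angle(ref, mov, theta, upsample=100)
    if final_err <= best_err:
        return final
    return best_t


def subtract_background(
    pair: SamplePair,
    t: RigidTransform,
    nuclear_channel: str = "DAPI",
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Register the background scan and subtract it from signal channels.

    The nuclear channel passes through unmodified.  Negative differences are
    clamped to 0 (unsigned image semantics).  Returns the corrected channel
    map and the registration validity mask.
    """
    corrected: dict[str, np.ndarray] = {}
    validity: np.ndarray | None = None
    for channel, original in pair.original.items():
        if channel == nuclear_channel:
            corrected[channel] = np.asarray(original, float)
            continue
        if channel not in pair.background:
            raise KeyError(f"background scan is missing channel {channel!r}")
        registered, valid = apply_rigid(pair.background[channel], t)
        corrected[channel] = np.clip(np.asarray(original, float) - registered, 0.0, None)
        validity = valid if validity is None else (validity & valid)
    if validity is None:
        validity = np.ones(next(iter(pair.original.values())).shape, bool)
    return corrected, validity
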