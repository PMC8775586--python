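"""Raw capture preprocessing: vignetting correction, impulse-noise removal,
projective registration, cropping, and min–max intensity normalization.

The fixed order of operations is: flat-field (vignetting) correction →
3×3 median filter → projective registration of the UV image onto the green
frame → crop to the in-focus region.  Min–max normalization to [0, 1]
happens at analysis time because the visual system adapts its operating
range to each scene.

Coordinate convention: 0-based (row, col) pixel indices; control points are
(x, y) = (col, row) pairs; crop rectangles are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp as _sk_warp

__all__ = [
    "SceneMetadata",
    "RawCapture",
    "ScenePair",
    "Homography",
    "correct_vignetting",
    "median3x3",
    "estimate_projective",
    "register_pair",
    "crop",
    "normalize_minmax",
    "relative_intensity_profiles",
]

ELEVATIONS = ("up", "down", "horizontal")


@dataclass(frozen=True)
class SceneMetadata:
    """Per-scene acquisition record (camera elevation, exposure, ND filter)."""

    stem: str
    elevation: str = "horizontal"
    exposure_s: float = 0.01
    nd_od: float = 0.0
    weather: str = ""
    distance: str = ""
    objects: str = ""
    date: str | None = None
    time: str | None = None

    def __post_init__(self) -> None:
        if self.elevation not in ELEVATIONS:
            raise ValueError(f"elevation must be one of {ELEVATIONS}")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.nd_od < 0:
            raise ValueError("nd_od must be >= 0")


@dataclass(frozen=True)
class RawCapture:
    """One raw 12-bit camera frame plus its channel tag and metadata."""

    image: np.ndarray
    channel: str  # "UV" or "Green"
    metadata: SceneMetadata

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("raw capture must be a 2-D array")
        if img.min() < 0 or img.max() > 4095:
            raise ValueError("raw values must lie in [0, 4095] (12-bit)")
        if min(img.shape) < 64:
            raise ValueError("raw capture must be at least 64x64")
        if self.channel not in ("UV", "Green"):
            raise ValueError("channel must be 'UV' or 'Green'")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class ScenePair:
    """Registered, same-shape UV and green images of one scene."""

    uv: np.ndarray
    green: np.ndarray
    metadata: SceneMetadata
    pixel_pitch_deg: float = 0.006
    normalized: bool = False
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        uv = np.asarray(self.uv, dtype=float)
        green = np.asarray(self.green, dtype=float)
        if uv.shape != green.shape:
            raise ValueError("uv and green must have identical shapes")
        if self.pixel_pitch_deg <= 0:
            raise ValueError("pixel_pitch_deg must be positive")
        if self.valid_mask is not None and self.valid_mask.shape != uv.shape:
            raise ValueError("valid_mask shape mismatch")
        object.__setattr__(self, "uv", uv)
        object.__setattr__(self, "green", green)

    @property
    def shape(self) -> tuple[int, int]:
        return self.uv.shape

    def angular_extent_deg(self) -> tuple[float, float]:
        """(vertical, horizontal) extent in degrees at the pixel pitch."""
        h, w = self.uv.shape
        return h * self.pixel_pitch_deg, w * self.pixel_pitch_deg


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform, scale fixed so the bottom-right entry is 1."""

    matrix: np.ndarray
    reprojection_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(M)) < 1e-12:
            raise ValueError("homography must be invertible")
        if M[2, 2] == 0:
            raise ValueError("cannot normalize: bottom-right entry is 0")
        object.__setattr__(self, "matrix", M / M[2, 2])

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        """Map (n, 2) array of (x, y) points through the homography."""
        pts = np.asarray(points_xy, dtype=float)
        ones = np.ones((pts.shape[0], 1))
        out = (self.matrix @ np.hstack([pts, ones]).T).T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))


def correct_vignetting(raw: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flat-field correction: raw * max(reference) / reference, pixelwise.

    ``reference`` is a flat-field capture of a uniformly illuminated target;
    dividing by its relative profile undoes the radial brightness falloff of
    the optics.  The max(reference) factor keeps the output on the original
    digital-number scale.
    """
    raw = np.asarray(raw, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if raw.shape != ref.shape:
        raise ValueError("raw and reference must have the same shape")
    n_bad = int(np.count_nonzero(ref <= 0))
    if n_bad:
        raise ValueError(
            f"reference image contains {n_bad} non-positive pixels; "
            "flat-field division is undefined there"
        )
    return raw * (ref.max() / ref)


def median3x3(image: np.ndarray) -> np.ndarray:
    """3x3 median filter (salt-and-pepper removal); reflect-padded borders."""
    return ndimage.median_filter(np.asarray(image, dtype=float), size=3, mode="reflect")


def estimate_projective(points_src: np.ndarray, points_dst: np.ndarray) -> Homography:
    """Least-squares homography from >= 4 point correspondences.

    Normalized direct linear transform (via scikit-image) minimizing the
    algebraic error; the per-point Euclidean reprojection error is attached
    to the returned ``Homography``.
    """
    src = np.asarray(points_src, dtype=float)
    dst = np.asarray(points_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("control points must be matching (n, 2) arrays")
    if src.shape[0] < 4:
        raise ValueError("need at least 4 correspondences for a homography")
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        if not tform or not np.all(np.isfinite(tform.params)):
            raise ValueError("degenerate control-point configuration")
    else:  # scikit-image < 0.26
        tform = ProjectiveTransform()
        if not tform.estimate(src, dst) or not np.all(np.isfinite(tform.params)):
            raise ValueError("degenerate control-point configuration")
    hom = Homography(tform.params)
    resid = np.linalg.norm(hom.apply(src) - dst, axis=1)
    return replace(hom, reprojection_errors=resid)


def register_pair(
    uv: np.ndarray,
    green: np.ndarray,
    h: Homography,
    order: int = 1,
    min_overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample the UV image onto the green pixel grid.

    ``h`` maps UV (x, y) coordinates into the green frame, so the UV value
    at an output (green-frame) pixel q is looked up at h^-1(q) by inverse
    mapping with bilinear interpolation (``order=0`` for nearest-neighbour).
    Returns ``(uv_registered, green, valid_mask)`` where the mask flags
    pixels whose pre-image fell inside the UV frame; out-of-view pixels are
    NaN in ``uv_registered`` and must be excluded by cropping.
    """
    uv = np.asarray(uv, dtype=float)
    green = np.asarray(green, dtype=float)
    inv_map = ProjectiveTransform(matrix=np.linalg.inv(h.matrix))
    uv_reg = _sk_warp(
        uv,
        inv_map,
        output_shape=green.shape,
        order=order,
        mode="constant",
        cval=np.nan,
        preserve_range=True,
    )
    valid = np.isfinite(uv_reg)
    if valid.mean() < min_overlap:
        raise ValueError(
            f"registration leaves only {valid.mean():.0%} valid overlap "
            f"(< {min_overlap:.0%})"
        )
    return uv_reg, green, valid


def crop(pair: ScenePair, rect: tuple[int, int, int, int]) -> ScenePair:
    """Crop both channels identically; rect = (row0, row1, col0, col1), half-open."""
    r0, r1, c0, c1 = rect
    h, w = pair.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"empty or out-of-bounds crop rect {rect} for shape {(h, w)}")
    mask = None if pair.valid_mask is None else pair.valid_mask[r0:r1, c0:c1]
    return replace(
        pair,
        uv=pair.uv[r0:r1, c0:c1],
        green=pair.green[r0:r1, c0:c1],
        valid_mask=mask,
    )


def _minmax(channel: np.ndarray, name: str) -> np.ndarray:
    lo, hi = np.nanmin(channel), np.nanmax(channel)
    if hi == lo:
        raise ValueError(f"{name} channel is constant; min-max normalization undefined")
    return (channel - lo) / (hi - lo)


def normalize_minmax(pair: ScenePair) -> ScenePair:
    """Map each channel independently to [0, 1] (subtract min, divide by max).

    Models the light adaptation of the visual system to the intensity range
    of each scene; all downstream statistics consume normalized images.
    """
    return replace(
        pair,
        uv=_minmax(pair.uv, "uv"),
        green=_minmax(pair.green, "green"),
        normalized=True,
    )


def relative_intensity_profiles(
    captures: Iterable[RawCapture], axis: str = "vertical"
) -> dict[str, dict[str, np.ndarray]]:
    """Per-elevation-category median +/- IQR relative intensity profiles.

    Each image is corrected to a common photometric scale (divided by its
    exposure length, multiplied by 10^OD to undo the ND attenuation), then
    normalized by the grand mean over all images, and averaged along the
    off-axis direction to a 1-D profile.  Within a category, profiles are
    aligned before the median: horizontal-axis profiles are centred;
    vertical-axis profiles are aligned to the top edge for lower-field
    ("down") images, to the bottom edge for upper-field ("up") images, and
    centred for "horizontal" images.  Returns
    ``{category: {"position": ..., "median": ..., "q25": ..., "q75": ..., "n": ...}}``.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    caps = list(captures)
    if not caps:
        raise ValueError("no captures given")
    corrected = [
        cap.image.astype(float) / cap.metadata.exposure_s * 10.0**cap.metadata.nd_od
        for cap in caps
    ]
    grand_mean = float(np.mean([img.mean() for img in corrected]))
    corrected = [img / grand_mean for img in corrected]
    # profile along requested axis: average over the other axis
    profiles = [
        img.mean(axis=1) if axis == "vertical" else img.mean(axis=0)
        for img in corrected
    ]

    out: dict[str, dict[str, np.ndarray]] = {}
    for category in ELEVATIONS:
        profs = [
            p for p, c in zip(profiles, caps) if c.metadata.elevation == category
        ]
        if not profs:
            continue
        length = max(p.size for p in profs)
        stack = np.full((len(profs), length), np.nan)
        for i, p in enumerate(profs):
            if axis == "horizontal" or category == "horizontal":
                start = (length - p.size) // 2
            elif category == "down":  # lower field: align to top edge
                start = 0
            else:  # upper field: align to bottom edge
                start = length - p.size
            stack[i, start : start + p.size] = p
        out[category] = {
            "position": np.arange(length),
            "median": np.nanmedian(stack, axis=0),
            "q25": np.nanpercentile(stack, 25, axis=0),
            "q75": np.nanpercentile(stack, 75, axis=0),
            "n": np.array(len(profs)),
        }
    return out
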