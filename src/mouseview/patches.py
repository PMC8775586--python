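"""Circular-patch statistics: RMS (achromatic) contrast, chromatic contrast,
and local moments/entropy maps.

RMS contrast of a patch is sd/mean (population moments — a patch is an
exhaustive pixel set, not a sample).  Chromatic contrast is the pointwise
difference of the UV and green RMS-contrast maps; its left (C < 0) and
right (C > 0) tails are summarised by separate Weibull fits.

Patch statistics are evaluated on every centre whose full circular patch
(default radius 30 px, i.e. a 0.36 degree patch at 0.006 degrees/pixel)
lies inside the image; the moment maps are computed with FFT convolutions
of the image powers against the disk footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .firstorder import WeibullFit, fit_weibull

__all__ = [
    "PatchStatMap",
    "ChromaticContrastMap",
    "disk_footprint",
    "circular_patch_stats",
    "chromatic_contrast",
    "fit_chromatic_weibull",
]

STATISTICS = ("mean", "sd", "rms_contrast", "skewness", "kurtosis", "entropy")
_MEAN_EPS = 1e-6  # division guard for rms_contrast on near-zero patches


@dataclass(frozen=True)
class PatchStatMap:
    """One local statistic evaluated on the valid patch-centre grid."""

    statistic: str
    values: np.ndarray
    patch_radius_px: int
    channel: str = ""
    n_invalid: int = 0

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class ChromaticContrastMap:
    """C(x, y) = C_RMS_UV - C_RMS_Green on the common patch-centre grid."""

    values: np.ndarray
    patch_radius_px: int


def disk_footprint(radius_px: int) -> np.ndarray:
    """Boolean disk {(dx, dy): dx^2 + dy^2 <= radius^2} as a (2r+1)^2 array."""
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dx**2 + dy**2) <= r**2


def _disk_sums(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return signal.fftconvolve(img, footprint.astype(float), mode="valid")


def circular_patch_stats(
    channel: np.ndarray,
    radius_px: int = 30,
    statistic: str = "rms_contrast",
    channel_name: str = "",
    entropy_bins: int = 64,
) -> PatchStatMap:
    """Evaluate one local statistic over a sliding circular patch.

    ``statistic`` is one of mean, sd, rms_contrast (sd/mean), skewness and
    kurtosis (third/fourth standardized population moments; kurtosis is not
    excess, a Gaussian patch gives ~3), or entropy (-sum p log2 p of the
    patch intensity histogram, ``entropy_bins`` uniform bins over [0, 1]).
    Centres where the guard ``mean < 1e-6`` makes rms_contrast undefined
    are NaN and counted in ``n_invalid``; sd of a constant patch is exactly 0.
    """
    img = np.asarray(channel, dtype=float)
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fp = disk_footprint(radius_px)
    if img.shape[0] < fp.shape[0] or img.shape[1] < fp.shape[1]:
        raise ValueError("image smaller than the patch diameter")
    npix = int(fp.sum())

    if statistic == "entropy":
        if img.min() < 0 or img.max() > 1:
            raise ValueError("entropy requires a [0, 1]-normalized image")
        idx = np.minimum((img * entropy_bins).astype(int), entropy_bins - 1)
        out_shape = (img.shape[0] - fp.shape[0] + 1, img.shape[1] - fp.shape[1] + 1)
        ent = np.zeros(out_shape)
        for b in range(entropy_bins):
            cnt = np.rint(_disk_sums((idx == b).astype(float), fp))
            p = cnt / npix
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(p > 0, p * np.log2(p), 0.0)
            ent -= term
        # clip tiny negative round-off
        return PatchStatMap("entropy", np.maximum(ent, 0.0), radius_px, channel_name)

    s1 = _disk_sums(img, fp) / npix
    if statistic == "mean":
        return PatchStatMap("mean", s1, radius_px, channel_name)
    s2 = _disk_sums(img**2, fp) / npix
    var = np.maximum(s2 - s1**2, 0.0)
    # FFT round-off leaves ~1e-16 relative residue on constant patches
    var[var <= 1e-12 * np.abs(s2)] = 0.0
    sd = np.sqrt(var)
    if statistic == "sd":
        return PatchStatMap("sd", sd, radius_px, channel_name)
    if statistic == "rms_contrast":
        invalid = s1 < _MEAN_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            rms = np.where(invalid, np.nan, sd / s1)
        return PatchStatMap(
            "rms_contrast", rms, radius_px, channel_name,
            n_invalid=int(invalid.sum()),
        )
    s3 = _disk_sums(img**3, fp) / npix
    if statistic == "skewness":
        m3 = s3 - 3.0 * s1 * s2 + 2.0 * s1**3
        invalid = sd == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(invalid, np.nan, m3 / sd**3)
        return PatchStatMap(
            "skewness", skew, radius_px, channel_name, n_invalid=int(invalid.sum())
        )
    s4 = _disk_sums(img**4, fp) / npix
    m4 = s4 - 4.0 * s1 * s3 + 6.0 * s1**2 * s2 - 3.0 * s1**4
    invalid = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(invalid, np.nan, m4 / var**2)
    return PatchStatMap(
        "kurtosis", kurt, radius_px, channel_name, n_invalid=int(invalid.sum())
    )


def chromatic_contrast(
    uv_map: PatchStatMap, green_map: PatchStatMap
) -> ChromaticContrastMap:
    """Pointwise UV - Green difference of two RMS-contrast maps."""
    for m in (uv_map, green_map):
        if m.statistic != "rms_contrast":
            raise ValueError("chromatic contrast is defined on rms_contrast maps")
    if uv_map.values.shape != green_map.values.shape:
        raise ValueError("patch-centre grids do not match")
    if uv_map.patch_radius_px != green_map.patch_radius_px:
        raise ValueError("patch radii do not match")
    return ChromaticContrastMap(
        uv_map.values - green_map.values, uv_map.patch_radius_px
    )


def fit_chromatic_weibull(
    cmap: ChromaticContrastMap, min_side: int = 20
) -> dict[str, WeibullFit | None]:
    """Separate Weibull fits to the two tails of the chromatic distribution.

    The right fit uses {C : C > 0}, the left fit uses {|C| : C < 0}; exact
    zeros belong to neither side.  A side with fewer than ``min_side``
    values is reported as None (flagged absent).  Returns
    ``{"left": ..., "right": ..., "n_left": ..., "n_right": ...}``.
    """
    c = cmap.values[np.isfinite(cmap.values)].ravel()
    right_vals = c[c > 0]
    left_vals = -c[c < 0]
    out: dict[str, WeibullFit | None] = {
        "n_left": left_vals.size,
        "n_right": right_vals.size,
    }
    out["right"] = fit_weibull(right_vals) if right_vals.size >= min_side else None
    out["left"] = fit_weibull(left_vals) if left_vals.size >= min_side else None
    return out
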