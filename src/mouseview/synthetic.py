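"""Synthetic two-channel (UV/green) scene generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes of real
co-acquired UV/green image pairs: per-channel 1/omega^a spatial power
spectra, bimodal ("sky above the horizon") or right-skewed unimodal
("ground clutter") intensity distributions, a shared multiplicative
vignetting field, a small projective misalignment of the green camera,
exposure and neutral-density intensity scaling, 12-bit quantization, and
salt-and-pepper sensor noise.

Both channels of a scene are shaped from the *same* white-noise innovation
field (with channel-specific spectral slopes), so they depict one scene the
way two co-registered cameras do; this is what makes per-scene paired
channel comparisons meaningful downstream.

One global seed fans out into independent per-stage substreams
(`numpy.random.SeedSequence.spawn`), so each stage is individually
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SyntheticSceneParams",
    "GroundTruth",
    "spectral_field",
    "make_scene_pair",
    "sample_weibull",
    "make_control_points",
]

MAX_DN = 4095  # 12-bit full scale, stored in a 16-bit container

# stage indices for the per-stage RNG substreams
_STAGES = {
    "white_noise": 0,
    "horizon_mask": 1,
    "sky_field": 2,
    "noise_uv": 3,
    "noise_green": 4,
    "control_points": 5,
    "white_noise_green": 6,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES[stage]])


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Knobs of one synthetic scene; defaults emulate an "upper-field" scene.

    Slopes are the target power-law exponents a of the 1/omega^a spatial
    power spectrum (natural scenes have a ~ 2).  ``intensity_mode`` selects
    the intensity statistics: ``bimodal_sky`` composites bright sky and
    darker objects through a smoothed random horizon, ``skewed_ground``
    applies a convex remap producing a right-skewed unimodal histogram.
    """

    height_px: int = 256
    width_px: int = 256
    slope_uv: float = 2.0
    slope_green: float = 2.0
    intensity_mode: str = "bimodal_sky"
    bimodal_separation: float = 0.5
    bimodal_separation_green: float | None = None  # None -> same as UV
    channel_noise: str = "shared"  # "shared" or "independent" innovations
    vignette_strength: float = 0.3
    sp_noise_fraction: float = 0.002
    homography: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )  # maps UV pixel coords to green pixel coords
    exposure_s: float = 0.01
    nd_od: float = 0.0
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.slope_uv < 0 or self.slope_green < 0:
            raise ValueError("spectral slopes must be >= 0")
        if not (0.0 <= self.sp_noise_fraction <= 0.05):
            raise ValueError("sp_noise_fraction must lie in [0, 0.05]")
        if self.intensity_mode not in ("bimodal_sky", "skewed_ground"):
            raise ValueError(f"unknown intensity_mode {self.intensity_mode!r}")
        if self.channel_noise not in ("shared", "independent"):
            raise ValueError("channel_noise must be 'shared' or 'independent'")
        if self.bit_depth != 12:
            raise ValueError("bit_depth is fixed at 12")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.nd_od < 0:
            raise ValueError("nd_od must be >= 0")
        H = np.asarray(self.homography, dtype=float)
        if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("homography must be an invertible 3x3 matrix")
        object.__setattr__(self, "homography", H)


@dataclass
class GroundTruth:
    """Everything needed to check the pipeline against the generator."""

    clean_uv: np.ndarray
    clean_green: np.ndarray
    vignette_field: np.ndarray
    homography: np.ndarray
    sky_mask: np.ndarray | None
    params: SyntheticSceneParams
    clip_fraction_uv: float = 0.0
    clip_fraction_green: float = 0.0
    clip_warning: bool = False


def spectral_field(
    shape: tuple[int, int],
    slope_a: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random field with expected power spectrum proportional to 1/omega^a.

    White Gaussian noise is shaped in the frequency domain by an amplitude
    factor omega^(-a/2) (omega the radial frequency in cycles/pixel), the DC
    component is zeroed (it would carry infinite power for a > 0), and the
    result is affinely mapped to [0, 1].
    """
    if slope_a < 0:
        raise ValueError("slope_a must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = shape
    white = rng.standard_normal((h, w))
    return shape_to_slope(white, slope_a)


def shape_to_slope(white: np.ndarray, slope_a: float) -> np.ndarray:
    """Impose a 1/omega^slope_a power spectrum on a white-noise field."""
    h, w = white.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    omega = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(omega > 0, omega ** (-slope_a / 2.0), 0.0)
    shaped = np.fft.ifft2(np.fft.fft2(white) * amp).real
    lo, hi = shaped.min(), shaped.max()
    if hi == lo:  # slope 0 with degenerate input; keep contract of [0,1]
        return np.zeros_like(shaped)
    return (shaped - lo) / (hi - lo)


def _vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Smooth radial falloff, 1 at the centre, (1-strength) at the corners."""
    h, w = shape
    y = (np.arange(h) - (h - 1) / 2.0) / ((h - 1) / 2.0)
    x = (np.arange(w) - (w - 1) / 2.0) / ((w - 1) / 2.0)
    r2 = (y[:, None] ** 2 + x[None, :] ** 2) / 2.0  # corners -> 1
    v = 1.0 - strength * r2
    return v / v.max()


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _apply_intensity_mode(
    base: np.ndarray,
    params: SyntheticSceneParams,
    seed: int,
    separation: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Map a [0,1] field to the target intensity statistics.

    bimodal_sky: composite a bright "sky" plateau and a darker textured
    "ground/object" component through a smoothed random horizon mask, the
    two mode centres separated by ``bimodal_separation`` (normalized units).
    A larger separation means stronger sky/object (silhouette) contrast —
    the channel-specific knob behind "higher contrast in UV" scenes.
    skewed_ground: convex remap u^3 -> right-skewed unimodal histogram.
    """
    if params.intensity_mode == "skewed_ground":
        return base**3, None
    sep = params.bimodal_separation if separation is None else separation
    rng = _stage_rng(seed, "horizon_mask")
    h, w = base.shape
    # random smooth horizon: rows above it are sky, softened over ~8% height
    horizon = rng.uniform(0.3, 0.7) * h
    wobble = spectral_field((1, w), 2.0, rng)[0] * 0.1 * h
    rows = np.arange(h)[:, None]
    soft = 0.08 * h
    mask = _smoothstep((horizon + wobble[None, :] - rows) / soft)  # 1 = sky
    hi = 0.5 + sep / 2.0
    lo = 0.5 - sep / 2.0
    amp = (1.0 - sep) / 2.0
    sky = hi + amp * (spectral_field(base.shape, 3.0, _stage_rng(seed, "sky_field")) - 0.5)
    ground = lo + amp * (base - 0.5) * 2.0
    out = np.clip(mask * sky + (1.0 - mask) * ground, 0.0, 1.0)
    return out, mask > 0.5


def _salt_and_pepper(
    img: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    if fraction <= 0:
        return img
    out = img.copy()
    n = int(round(fraction * img.size))
    if n == 0:
        return out
    idx = rng.choice(img.size, size=n, replace=False)
    vals = np.where(rng.random(n) < 0.5, 0, MAX_DN)
    out.flat[idx] = vals
    return out


def _quantize(img: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip to [0, 4095] and floor to integer; return the clipped fraction."""
    clipped = np.count_nonzero((img < 0) | (img > MAX_DN)) / img.size
    return np.floor(np.clip(img, 0, MAX_DN)).astype(np.uint16), clipped


def make_scene_pair(
    params: SyntheticSceneParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Generate one raw UV/green pair, its flat-field reference, and truth.

    Returns ``(raw_uv, raw_green, reference, truth)``.  Raw images are
    12-bit uint16 arrays.  The green channel is the scene resampled through
    the *inverse* of ``params.homography`` (which maps UV coordinates to
    green coordinates), so registering the raw UV image with that homography
    aligns the pair.  The reference is the vignette field at full scale
    (float, undegraded), standing in for a flat-field capture.
    """
    from skimage.transform import ProjectiveTransform, warp

    h, w = params.height_px, params.width_px
    white = _stage_rng(params.seed, "white_noise").standard_normal((h, w))
    if params.channel_noise == "shared":
        white_green = white  # same scene seen through two spectral bands
    else:
        white_green = _stage_rng(params.seed, "white_noise_green").standard_normal((h, w))
    clean_uv, sky_mask = _apply_intensity_mode(
        shape_to_slope(white, params.slope_uv), params, params.seed
    )
    clean_green, _ = _apply_intensity_mode(
        shape_to_slope(white_green, params.slope_green), params, params.seed,
        separation=params.bimodal_separation_green,
    )

    vign = _vignette((h, w), params.vignette_strength)
    # exposure -> linear gain; ND filter attenuates the green channel only.
    # Headroom of 0.9 at the reference exposure keeps clipping negligible,
    # mirroring the acquisition rule of no under/over-exposed pixels.
    gain = MAX_DN * 0.9 * (params.exposure_s / 0.01)
    uv_counts = clean_uv * vign * gain
    # green pixel q images the scene point H^-1(q); warp's map is output->input
    tform = ProjectiveTransform(matrix=np.linalg.inv(params.homography))
    green_warped = warp(
        clean_green, tform, order=1, mode="reflect", preserve_range=True
    )
    green_counts = green_warped * vign * gain * 10.0 ** (-params.nd_od)

    raw_uv, clip_uv = _quantize(uv_counts)
    raw_green, clip_green = _quantize(green_counts)
    raw_uv = _salt_and_pepper(
        raw_uv, params.sp_noise_fraction, _stage_rng(params.seed, "noise_uv")
    )
    raw_green = _salt_and_pepper(
        raw_green, params.sp_noise_fraction, _stage_rng(params.seed, "noise_green")
    )

    clip_uv, clip_green = float(clip_uv), float(clip_green)
    clip_warn = bool(max(clip_uv, clip_green) > 1e-3)
    if clip_warn:
        warnings.warn(
            f"scene seed={params.seed}: clipped fraction "
            f"uv={clip_uv:.2%} green={clip_green:.2%}",
            stacklevel=2,
        )
    truth = GroundTruth(
        clean_uv=clean_uv,
        clean_green=clean_green,
        vignette_field=vign,
        homography=params.homography,
        sky_mask=sky_mask,
        params=params,
        clip_fraction_uv=clip_uv,
        clip_fraction_green=clip_green,
        clip_warning=clip_warn,
    )
    reference = vign * MAX_DN
    return raw_uv, raw_green, reference, truth


def study_params(
    category: str,
    seed: int,
    height_px: int = 160,
    width_px: int = 160,
    **overrides,
) -> SyntheticSceneParams:
    """Standard study conditions for one scene of a given visual-field category.

    "up" (upper-field) scenes are bimodal sky/object composites in which the
    UV channel has the stronger silhouette contrast (mode separation 0.7 vs
    0.35 for green; shared 1/omega^2 texture) — dark objects against a
    UV-bright sky.  "down" (lower-field) scenes are right-skewed ground
    clutter in which the green channel carries the shallower spectral slope
    (2.0 vs 3.0 for UV) and hence the wider contrast distribution.
    "horizontal" scenes are channel-symmetric.  In every category the two
    channels share one innovation field, as co-acquired images of one scene
    do; a mild homography, vignetting and sensor noise are applied.
    """
    base = dict(
        height_px=height_px,
        width_px=width_px,
        vignette_strength=0.3,
        sp_noise_fraction=0.002,
        homography=np.array(
            [[1.0, 0.002, 3.0], [-0.001, 1.0, -2.0], [1e-6, 0.0, 1.0]]
        ),
        seed=seed,
    )
    if category == "up":
        base.update(
            intensity_mode="bimodal_sky",
            bimodal_separation=0.7,
            bimodal_separation_green=0.35,
            slope_uv=2.0,
            slope_green=2.0,
        )
    elif category == "down":
        base.update(
            intensity_mode="skewed_ground", slope_uv=3.0, slope_green=2.0
        )
    elif category == "horizontal":
        base.update(
            intensity_mode="skewed_ground", slope_uv=2.0, slope_green=2.0
        )
    else:
        raise ValueError(f"unknown category {category!r}")
    base.update(overrides)
    return SyntheticSceneParams(**base)


def null_params(seed: int, height_px: int = 160, width_px: int = 160,
                **overrides) -> SyntheticSceneParams:
    """A scene whose channels are statistically identical but independent.

    Used for type-I-error calibration of the comparison stage: both
    channels have the same spectral slope and intensity mode but
    independent innovation fields, so every channel difference is pure
    noise.
    """
    base = dict(
        height_px=height_px,
        width_px=width_px,
        intensity_mode="skewed_ground",
        slope_uv=2.0,
        slope_green=2.0,
        channel_noise="independent",
        vignette_strength=0.0,
        sp_noise_fraction=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticSceneParams(**base)


def sample_weibull(
    beta_scale: float, gamma_shape: float, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n values from the Weibull(scale beta, shape gamma) distribution.

    Inverse-CDF sampling, x = beta * (-ln(1 - U))^(1/gamma) — the canonical
    scale–shape parameterization used by the contrast-distribution fits.
    """
    if beta_scale <= 0 or gamma_shape <= 0:
        raise ValueError("beta_scale and gamma_shape must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    return beta_scale * (-np.log1p(-u)) ** (1.0 / gamma_shape)


def make_control_points(
    truth: GroundTruth,
    n_points: int = 12,
    jitter_px: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated manual control points consistent with the true homography.

    Returns ``(src, dst)`` arrays of (x, y) coordinates: points in the UV
    frame and their images in the green frame under ``truth.homography``,
    the latter perturbed by Gaussian jitter of scale ``jitter_px``
    (emulating hand-clicking error).  Near-collinear draws are rejected.
    """
    if n_points < 4:
        raise ValueError("need at least 4 control points for a homography")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = truth.clean_uv.shape
    H = truth.homography
    for _ in range(100):
        src = np.column_stack(
            [rng.uniform(0.1 * w, 0.9 * w, n_points), rng.uniform(0.1 * h, 0.9 * h, n_points)]
        )
        centered = src - src.mean(axis=0)
        # reject configurations that are (nearly) collinear
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] > 0.05 * min(h, w):
            break
    else:  # pragma: no cover - essentially impossible
        raise RuntimeError("failed to draw a non-degenerate point configuration")
    ones = np.ones((n_points, 1))
    dst_h = (H @ np.hstack([src, ones]).T).T
    dst = dst_h[:, :2] / dst_h[:, 2:3]
    if jitter_px > 0:
        dst = dst + rng.normal(0.0, jitter_px, dst.shape)
    return src, dst
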