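"""First-order image statistics: intensity histograms, Laplacian-of-Gaussian
local contrast, and two-parameter Weibull fits to contrast distributions.

Local contrast is measured with the Laplacian of a 2-D Gaussian,

    LoG(x, y) = 1/(pi sigma^4) (1 - (x^2+y^2)/(2 sigma^2))
                exp(-(x^2+y^2)/(2 sigma^2)),

a centre–surround operator mimicking early visual receptive fields, sampled
at integer offsets on [-3 sigma, 3 sigma] and mean-subtracted so the
discrete kernel sums exactly to zero.  The magnitude of the filter response
is summarised by a Weibull fit: the scale parameter beta tracks the width
of the contrast distribution (higher contrast) and the shape parameter
gamma its peakedness (smaller gamma, heavier tail).

Parameterization note: the fit reports the canonical *scale* beta
(density gamma/beta (x/beta)^(gamma-1) exp(-(x/beta)^gamma)), under which
"larger beta = wider distribution" holds; the equivalent rate parameter of
the form w(x) = b g x^(g-1) exp(-b x^g) is available as ``printed_rate``
(b = beta^-gamma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, signal

from .preprocess import ScenePair

__all__ = [
    "HistogramDist",
    "LoGKernel",
    "WeibullFit",
    "intensity_histogram",
    "log_kernel",
    "local_contrast_map",
    "fit_weibull",
    "contrast_weibull_per_scene",
]


@dataclass(frozen=True)
class HistogramDist:
    """Normalized-intensity histogram with the standard 0.01 bin size."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size != 100 or np.asarray(self.bin_edges).size != 101:
            raise ValueError("expected 100 bins on [0, 1]")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")


@dataclass(frozen=True)
class LoGKernel:
    """Discrete Laplacian-of-Gaussian kernel with exact zero sum.

    ``weights`` are the sampled analytic values minus their mean
    (``zero_sum_offset``), so a constant image maps exactly to zero.
    """

    sigma_px: float
    offsets: np.ndarray  # integer offsets in [-floor(3 sigma), floor(3 sigma)]
    weights: np.ndarray
    zero_sum_offset: float

    @property
    def support_px(self) -> int:
        return self.weights.shape[0]

    def support_deg(self, pixel_pitch_deg: float = 0.006) -> float:
        """Angular width of the filter support (6 sigma at the pixel pitch)."""
        return (self.offsets[-1] - self.offsets[0]) * pixel_pitch_deg


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit of a contrast-magnitude sample."""

    beta_scale: float
    gamma_shape: float
    n_samples: int
    loglik: float
    n_zeros_dropped: int = 0
    parameterization: str = "canonical_scale"

    def __post_init__(self) -> None:
        if self.beta_scale <= 0 or self.gamma_shape <= 0:
            raise ValueError("Weibull parameters must be positive")

    @property
    def printed_rate(self) -> float:
        """Rate-form parameter b of w(x) = b g x^(g-1) exp(-b x^g)."""
        return self.beta_scale**-self.gamma_shape


def intensity_histogram(
    channel: np.ndarray, validity_mask: np.ndarray | None = None
) -> HistogramDist:
    """Fraction of valid pixels per 0.01-wide intensity bin on [0, 1].

    The input must already be min–max normalized; the final bin is
    right-closed so an intensity of exactly 1.0 is counted.
    """
    img = np.asarray(channel, dtype=float)
    vals = img[validity_mask] if validity_mask is not None else img.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid pixels")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("channel is not normalized to [0, 1]")
    edges = np.linspace(0.0, 1.0, 101)
    counts, _ = np.histogram(vals, bins=edges)  # numpy closes the last bin
    return HistogramDist(edges, counts / vals.size)


def log_kernel(sigma_px: float) -> LoGKernel:
    """Laplacian-of-Gaussian kernel of width sigma (pixels).

    Sampled at integer offsets over [-3 sigma, 3 sigma]; the sampled values
    are mean-subtracted so the discrete kernel sums exactly to zero (the
    continuous LoG integrates to zero but its samples do not).
    """
    if sigma_px < 1:
        raise ValueError("sigma_px must be >= 1")
    r = int(np.floor(3 * sigma_px))
    offsets = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(offsets, offsets)
    rho2 = (xx**2 + yy**2) / (2.0 * sigma_px**2)
    raw = (1.0 / (np.pi * sigma_px**4)) * (1.0 - rho2) * np.exp(-rho2)
    offset = raw.mean()
    return LoGKernel(
        sigma_px=float(sigma_px),
        offsets=offsets,
        weights=raw - offset,
        zero_sum_offset=float(offset),
    )


def local_contrast_map(channel: np.ndarray, kernel: LoGKernel) -> np.ndarray:
    """Valid-region convolution of a normalized image with a LoG kernel.

    No padding is used, so no synthetic edge contrast enters the output; the
    map is smaller than the input by (support - 1) on each axis.
    """
    img = np.asarray(channel, dtype=float)
    k = kernel.support_px
    if img.shape[0] < k or img.shape[1] < k:
        raise ValueError(
            f"image {img.shape} smaller than kernel support {k} "
            f"(sigma={kernel.sigma_px})"
        )
    return signal.fftconvolve(img, kernel.weights, mode="valid")


def _weibull_loglik(x: np.ndarray, beta: float, gamma: float) -> float:
    return float(
        x.size * (np.log(gamma) - gamma * np.log(beta))
        + (gamma - 1.0) * np.log(x).sum()
        - ((x / beta) ** gamma).sum()
    )


def fit_weibull(samples: Iterable[float]) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit to positive magnitudes.

    Profile likelihood: for fixed shape gamma the conditional MLE of the
    scale is beta(gamma) = (mean(x^gamma))^(1/gamma); substituting reduces
    the problem to the scalar shape equation

        1/gamma + mean(ln x) - sum(x^gamma ln x) / sum(x^gamma) = 0,

    which is monotone in gamma and solved by bisection (Brent).  Zeros
    (structural, from flat image regions) are dropped and counted.
    """
    x = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                   dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("samples must be non-negative magnitudes")
    n_zeros = int(np.count_nonzero(x == 0))
    x = x[x > 0]
    if x.size < 20:
        raise ValueError(f"need >= 20 positive samples, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate sample: all values equal")

    # work on log scale for numerical stability of x^gamma
    logx = np.log(x)
    mean_logx = logx.mean()

    def shape_eq(gamma: float) -> float:
        w = np.exp(gamma * (logx - logx.max()))  # scaled x^gamma
        return 1.0 / gamma + mean_logx - float((w * logx).sum() / w.sum())

    lo, hi = 1e-3, 1.0
    while shape_eq(hi) > 0 and hi < 1e4:
        hi *= 2.0
    gamma = float(optimize.brentq(shape_eq, lo, hi, xtol=1e-10, rtol=1e-12))
    # beta = (mean(x^gamma))^(1/gamma), computed in log space
    m = logx.max()
    beta = float(np.exp(m + np.log(np.mean(np.exp(gamma * (logx - m)))) / gamma))
    return WeibullFit(
        beta_scale=beta,
        gamma_shape=gamma,
        n_samples=int(x.size),
        loglik=_weibull_loglik(x, beta, gamma),
        n_zeros_dropped=n_zeros,
    )


def contrast_weibull_per_scene(
    pair: ScenePair, sigmas: Iterable[float] = (5, 10, 20, 40)
) -> dict[tuple[str, float], WeibullFit]:
    """Weibull fits of |LoG response| for each channel and filter width.

    Returns ``{(channel, sigma): WeibullFit}`` for channel in {"UV",
    "Green"}.  The pair must be normalized and fully valid (cropped to the
    registered overlap).
    """
    if not pair.normalized:
        raise ValueError("pair must be min-max normalized first")
    if pair.valid_mask is not None and not pair.valid_mask.all():
        raise ValueError("crop the pair to its valid region before analysis")
    out: dict[tuple[str, float], WeibullFit] = {}
    for sigma in sigmas:
        kernel = log_kernel(sigma)
        for channel, img in (("UV", pair.uv), ("Green", pair.green)):
            try:
                out[(channel, float(sigma))] = fit_weibull(
                    np.abs(local_contrast_map(img, kernel)).ravel()
                )
            except ValueError as err:
                raise ValueError(
                    f"scene {pair.metadata.stem!r}, channel {channel}, "
                    f"sigma {sigma}: {err}"
                ) from err
    return out
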