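"""Second-order image statistics: 2-D power spectra, power-law (1/omega^a)
fits to the axis slices, and FFT-based spatial autocorrelation.

The power spectrum is S = |FFT(I)|^2 with no window or detrending, matching
the plain-FFT definition; natural scenes follow S ~ b/omega^a with a ~ 2
along spatial frequency omega.  The spatial autocorrelation follows the
Wiener–Khinchin theorem, R = IFFT[S] of the mean-subtracted image,
normalized by the zero-lag value so R(0,0) = 1 and values are correlation
coefficients.  Both use the circular (periodic) convention implicit in the
pure-FFT route; zero-padded linear autocorrelation is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PowerSpectrum2D",
    "PowerLawFit",
    "AutocorrMap",
    "power_spectrum",
    "axis_slices",
    "fit_powerlaw",
    "autocorrelation",
    "correlation_at",
]


@dataclass(frozen=True)
class PowerSpectrum2D:
    """DC-centred power spectrum; frequencies in cycles/pixel in (-0.5, 0.5]."""

    power: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of b/omega^a to a 1-D power slice in log-log space.

    ``intercept_b`` is raw power extrapolated to omega = 1 cycle/pixel (its
    log10 is the Y-intercept of the log-log regression line); ``slope_a``
    is the positive spectral-decay exponent.
    """

    slope_a: float
    intercept_b: float
    fit_range: tuple[float, float]
    r_squared: float
    n_points: int
    n_dropped_zero_power: int = 0


@dataclass(frozen=True)
class AutocorrMap:
    """Normalized spatial autocorrelation, DC-centred; R(0, 0) = 1."""

    values: np.ndarray
    offsets_x: np.ndarray
    offsets_y: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1.0 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")


def power_spectrum(channel: np.ndarray, subtract_mean: bool = False) -> PowerSpectrum2D:
    """2-D power spectral density S = |FFT(I)|^2, DC-centred.

    Default is the as-printed convention (no window, no detrend, DC
    retained); ``subtract_mean=True`` removes the image mean first (used on
    the autocorrelation path).  Unnormalized-transform Parseval convention:
    sum(S) = N * sum(I^2).
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("need a 2-D image with both sides >= 8")
    if subtract_mean:
        img = img - img.mean()
    f = np.fft.fft2(img)
    power = np.fft.fftshift(np.abs(f) ** 2)
    h, w = img.shape
    return PowerSpectrum2D(
        power=power,
        freq_x=np.fft.fftshift(np.fft.fftfreq(w)),
        freq_y=np.fft.fftshift(np.fft.fftfreq(h)),
    )


def axis_slices(
    spec: PowerSpectrum2D,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Positive-frequency central slices S(omega_x, 0) and S(0, omega_y).

    Returns ``{"horizontal": (freq, power), "vertical": (freq, power)}``
    with DC excluded; slice lengths are floor(N/2) per axis.
    """
    iy0 = int(np.argmin(np.abs(spec.freq_y)))
    ix0 = int(np.argmin(np.abs(spec.freq_x)))
    horiz_f = spec.freq_x[ix0 + 1 :]
    horiz_p = spec.power[iy0, ix0 + 1 :]
    vert_f = spec.freq_y[iy0 + 1 :]
    vert_p = spec.power[iy0 + 1 :, ix0]
    # frequencies live in (-0.5, 0.5]: for even sizes the Nyquist bin sits at
    # -0.5 after the shift and belongs to the positive half (S(-0.5)=S(0.5))
    if spec.freq_x[0] == -0.5:
        horiz_f = np.append(horiz_f, 0.5)
        horiz_p = np.append(horiz_p, spec.power[iy0, 0])
    if spec.freq_y[0] == -0.5:
        vert_f = np.append(vert_f, 0.5)
        vert_p = np.append(vert_p, spec.power[0, ix0])
    return {"horizontal": (horiz_f, horiz_p), "vertical": (vert_f, vert_p)}


def fit_powerlaw(freq: np.ndarray, power: np.ndarray) -> PowerLawFit:
    """Ordinary least squares of log10(power) on log10(freq).

    Fits S(omega) = b / omega^a over all supplied positive frequencies
    (equal weight per FFT bin); bins with non-positive power are dropped
    and counted.  Exact on exact power-law input.
    """
    freq = np.asarray(freq, dtype=float)
    power = np.asarray(power, dtype=float)
    if freq.shape != power.shape or freq.ndim != 1:
        raise ValueError("freq and power must be matching 1-D arrays")
    if np.any(freq <= 0):
        raise ValueError("frequencies must be positive (exclude DC)")
    keep = power > 0
    n_dropped = int((~keep).sum())
    freq, power = freq[keep], power[keep]
    if freq.size < 8:
        raise ValueError(f"need >= 8 usable points, got {freq.size}")
    lx, ly = np.log10(freq), np.log10(power)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(
        slope_a=float(-slope),
        intercept_b=float(10.0**intercept),
        fit_range=(float(freq.min()), float(freq.max())),
        r_squared=max(min(r2, 1.0), 0.0),
        n_points=int(freq.size),
        n_dropped_zero_power=n_dropped,
    )


def autocorrelation(channel: np.ndarray, pad: bool = False) -> AutocorrMap:
    """Spatial autocorrelation via the Wiener–Khinchin theorem.

    The image mean is subtracted, S = |FFT|^2 is inverted, and the result
    is divided by the zero-lag value, giving correlation coefficients with
    R(0, 0) = 1.  Default is circular (periodic) autocorrelation; with
    ``pad=True`` the image is zero-padded to twice its size, giving the
    linear (non-wrapped) estimate.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError("need a 2-D image with both sides >= 8")
    img = img - img.mean()
    if not np.any(img):
        raise ValueError("constant image: autocorrelation undefined (zero variance)")
    h, w = img.shape
    if pad:
        f = np.fft.fft2(img, s=(2 * h, 2 * w))
    else:
        f = np.fft.fft2(img)
    r = np.fft.ifft2(np.abs(f) ** 2).real
    r = r / r[0, 0]
    r = np.fft.fftshift(r)
    hh, ww = r.shape
    return AutocorrMap(
        values=np.clip(r, -1.0, 1.0),
        offsets_x=np.arange(ww) - ww // 2,
        offsets_y=np.arange(hh) - hh // 2,
    )


def correlation_at(acf: AutocorrMap, d_h: int, d_v: int) -> float:
    """R at horizontal offset d_h (pixels, columns) and vertical offset d_v."""
    ix = np.flatnonzero(acf.offsets_x == d_h)
    iy = np.flatnonzero(acf.offsets_y == d_v)
    if ix.size == 0 or iy.size == 0:
        raise ValueError(f"offset ({d_h}, {d_v}) outside the autocorrelation map")
    return float(acf.values[iy[0], ix[0]])
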