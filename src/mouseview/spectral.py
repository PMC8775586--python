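"""Spectral sensitivity model of the mouse eye and the two-channel camera.

The mouse retina is dichromatic: S-opsin peaks in the near UV (~360 nm) and
M-opsin in the green (~508 nm).  This module models photoreceptor absorption
with the A1 visual-pigment nomogram, composes it with ocular (or camera
optics) transmittance, summarises the resulting bands by their peak and
half-width at half maximum, and provides the back-of-the-envelope photon
budget and angular-sampling estimates for photopic mouse vision.

All curves are relative: after any operation the result is renormalized to a
peak of 1.  Curves living on different wavelength grids are linearly
interpolated onto the union grid restricted to their common support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "load_bundled_curve",
    "SpectralCurve",
    "ChannelBand",
    "EyeGeometry",
    "govardovskii_alpha",
    "pigment_template",
    "apply_transmittance",
    "channel_sensitivity",
    "peak_and_hwhm",
    "photoreceptor_photon_flux",
    "angular_sampling_resolution",
]


@dataclass(frozen=True)
class SpectralCurve:
    """Relative spectral amplitude sampled on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D of equal length")
        if wl.size < 2:
            raise ValueError("a spectral curve needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def normalized(self) -> "SpectralCurve":
        """Rescale so the maximum value is 1."""
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero curve")
        return SpectralCurve(self.wavelengths_nm, self.values / peak)

    def interp(self, grid_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the sampled support."""
        return np.interp(grid_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)

    # -- two-column CSV (header wavelength_nm,value; '#' comments) ---------
    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralCurve":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("wavelength"):
                    continue
                wl, val = line.split(",")[:2]
                rows.append((float(wl), float(val)))
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,value\n")
            for wl, val in zip(self.wavelengths_nm, self.values):
                fh.write(f"{wl:.6g},{val:.8g}\n")


@dataclass(frozen=True)
class ChannelBand:
    """Peak wavelength and half-width at half maximum of a sensitivity band."""

    center_nm: float
    hwhm_nm: float
    one_sided: bool = False  # set when only one half-max crossing exists

    def __post_init__(self) -> None:
        if self.center_nm <= 0 or self.hwhm_nm <= 0:
            raise ValueError("center_nm and hwhm_nm must be positive")


@dataclass(frozen=True)
class EyeGeometry:
    """Geometry and optics of the mouse eye used in the photon budget.

    Defaults are the photopic daylight estimates for mouse: ambient photon
    flux Phi (photons/um^2/s, dim end of 1e3-1e5 lux daylight), 0.5 mm pupil,
    4 mm eye, 50% ocular transmittance, 0.5 um^2 photoreceptor collection
    area, and mean cone / rod densities of 12,400 and 437,000 cells/mm^2.
    """

    illuminance_flux_phi: float = 1e7
    pupil_diameter_mm: float = 0.5
    eye_diameter_mm: float = 4.0
    transmittance: float = 0.5
    photoreceptor_area_um2: float = 0.5
    cone_density_per_mm2: float = 12_400.0
    rod_density_per_mm2: float = 437_000.0

    def __post_init__(self) -> None:
        for name in (
            "illuminance_flux_phi",
            "pupil_diameter_mm",
            "eye_diameter_mm",
            "transmittance",
            "photoreceptor_area_um2",
            "cone_density_per_mm2",
            "rod_density_per_mm2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.transmittance > 1:
            raise ValueError("transmittance must be <= 1")


def load_bundled_curve(name: str) -> SpectralCurve:
    """Load one of the packaged reference curves by file stem.

    Available: ``sensor_qe_synthetic`` (Gaussian stand-in for a camera
    sensor QE curve) and ``ocular_media_transmittance_synthetic``
    (logistic short-pass-absorber stand-in for whole-eye transmittance).
    Both are synthetic constructions, not measured data; real measured
    curves are user-supplied via :meth:`SpectralCurve.from_csv`.
    """
    from importlib.resources import files

    path = files("mouseview.data") / f"{name}.csv"
    if not path.is_file():
        raise FileNotFoundError(f"no bundled curve named {name!r}")
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("wavelength"):
            continue
        wl, val = line.split(",")[:2]
        rows.append((float(wl), float(val)))
    arr = np.array(rows, dtype=float)
    return SpectralCurve(arr[:, 0], arr[:, 1])


def govardovskii_alpha(wavelength_nm, lambda_max_nm: float):
    """A1 pigment alpha-band template value at ``wavelength_nm``.

    Standard vitamin-A1 nomogram: with x = lambda_max / lambda,

        S(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)

    with A=69.7, B=28, C=-14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459 exp(-(lambda_max - 300)^2 / 11940).
    Accepts scalars or arrays; not normalized (S(lambda_max) is ~1 already).
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    x = lambda_max_nm / wl
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    denom = np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
    out = 1.0 / denom
    return out if out.ndim else float(out)


def pigment_template(lambda_max_nm: float, grid_nm) -> SpectralCurve:
    """Sample the A1 pigment nomogram on ``grid_nm``, normalized to peak 1.

    ``lambda_max_nm`` must lie within the span of the grid (e.g. 360 nm for
    mouse S-opsin, 508 nm for M-opsin).
    """
    grid = np.asarray(grid_nm, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if not (grid[0] <= lambda_max_nm <= grid[-1]):
        raise ValueError(
            f"lambda_max {lambda_max_nm} nm outside grid span "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    vals = govardovskii_alpha(grid, lambda_max_nm)
    return SpectralCurve(grid, vals).normalized()


def _common_grid(c1: SpectralCurve, c2: SpectralCurve) -> np.ndarray:
    lo = max(c1.wavelengths_nm[0], c2.wavelengths_nm[0])
    hi = min(c1.wavelengths_nm[-1], c2.wavelengths_nm[-1])
    if lo >= hi:
        raise ValueError("spectral curves have disjoint wavelength supports")
    grid = np.union1d(c1.wavelengths_nm, c2.wavelengths_nm)
    return grid[(grid >= lo) & (grid <= hi)]


def _pointwise_product(c1: SpectralCurve, c2: SpectralCurve) -> SpectralCurve:
    grid = _common_grid(c1, c2)
    vals = c1.interp(grid) * c2.interp(grid)
    return SpectralCurve(grid, vals).normalized()


def apply_transmittance(
    sensitivity: SpectralCurve, transmittance: SpectralCurve
) -> SpectralCurve:
    """Correct a sensitivity curve by a media-transmittance curve.

    Pointwise product on the union grid restricted to the common support,
    renormalized to peak 1.  Because the ocular media absorb short
    wavelengths more strongly, this shifts the S-pigment peak a few nm to
    longer wavelengths.
    """
    return _pointwise_product(sensitivity, transmittance)


def channel_sensitivity(
    optics_transmission: SpectralCurve, sensor_qe: SpectralCurve
) -> SpectralCurve:
    """Effective sensitivity of one camera channel.

    The composition of filter/optics transmission with sensor quantum
    efficiency is a pointwise spectral product (each wavelength is
    attenuated then detected independently).
    """
    return _pointwise_product(optics_transmission, sensor_qe)


def peak_and_hwhm(curve: SpectralCurve) -> ChannelBand:
    """Locate the peak and half-width at half maximum of a band.

    The centre is the wavelength of the maximum (lowest wavelength on a
    plateau); the HWHM is half the distance between the two half-maximum
    crossings, found by linear interpolation between samples.  If the curve
    never falls below half maximum on one side, the one-sided HWHM is
    returned with ``one_sided=True``.
    """
    wl, vals = curve.wavelengths_nm, curve.values
    i_peak = int(np.argmax(vals))
    peak = vals[i_peak]
    half = peak / 2.0

    def _crossing(idx_range) -> float | None:
        # walk away from the peak; interpolate the first descent through half
        prev = i_peak
        for i in idx_range:
            if vals[i] <= half:
                w0, w1 = wl[prev], wl[i]
                v0, v1 = vals[prev], vals[i]
                if v1 == v0:
                    return w1
                return w0 + (half - v0) * (w1 - w0) / (v1 - v0)
            prev = i
        return None

    left = _crossing(range(i_peak - 1, -1, -1))
    right = _crossing(range(i_peak + 1, len(wl)))
    center = float(wl[i_peak])
    if left is not None and right is not None:
        return ChannelBand(center, (right - left) / 2.0)
    if left is None and right is None:
        raise ValueError("curve never crosses half maximum on either side")
    width = (center - left) if right is None else (right - center)
    return ChannelBand(center, width, one_sided=True)


def photoreceptor_photon_flux(geom: EyeGeometry) -> float:
    """Photon flux on a single photoreceptor (photons/photoreceptor/s).

    Phi * A_pupil / A_retina * T * A_photoreceptor, with the pupil a disk of
    diameter d_pupil and the retina covering half the inner sphere of the
    eye, A_retina = 4 pi (d_eye/2)^2 / 2.  The mm^2 areas enter only as a
    ratio, so the um^2 photoreceptor area fixes the output units.
    """
    a_pupil = math.pi * (geom.pupil_diameter_mm / 2.0) ** 2
    a_retina = 4.0 * math.pi * (geom.eye_diameter_mm / 2.0) ** 2 / 2.0
    return (
        geom.illuminance_flux_phi
        * (a_pupil / a_retina)
        * geom.transmittance
        * geom.photoreceptor_area_um2
    )


def angular_sampling_resolution(
    density_per_mm2: float, eye_diameter_mm: float
) -> float:
    """Angular spacing (degrees) of a photoreceptor lattice of given density.

    One lattice spacing 1/sqrt(rho) viewed at the posterior nodal distance
    d_eye/2: (180/pi) * (1/sqrt(rho)) / (d_eye/2).  For the mouse cone
    density of 12,400 cells/mm^2 and a 4 mm eye this gives ~0.26 degrees,
    the photopic "pixel size" of mouse vision; rods (~437,000 cells/mm^2)
    would support ~0.04 degrees.
    """
    if density_per_mm2 <= 0:
        raise ValueError("density must be positive")
    spacing_mm = 1.0 / math.sqrt(density_per_mm2)
    return math.degrees(spacing_mm / (eye_diameter_mm / 2.0))
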