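"""Retinal stimulus optics: diffraction-limited PSF with residual defocus,
retinal light distribution of a square flash, and Gaussian cone apertures.

The point spread function is computed by Fourier optics from a circular
pupil.  Residual defocus enters as a quadratic wavefront with
peak-to-valley error D * r_pupil^2 / 2 (D in diopters, r in meters), the
standard small-angle physiological-optics convention.  All grids carry
angular coordinates in arcmin and all distributions are normalized to
unit volume so that aperture-weighted integrals read out directly as
effective cone counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, ResolutionError
from .mosaic import ConeMosaic

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi

#: Gaussian FWHM of the cone aperture, arcmin
DEFAULT_APERTURE_FWHM = 0.59
#: instrument angular sampling, arcmin per pixel
DEFAULT_PIXEL_PITCH = 0.11

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _grid_coords(grid_size: int, pixel_pitch: float) -> np.ndarray:
    """Centred 1-D angular coordinates (arcmin) of a square grid."""
    return (np.arange(grid_size) - grid_size // 2) * pixel_pitch


@dataclass
class PointSpreadFunction:
    """Unit-volume PSF sampled on a square angular grid."""

    grid: np.ndarray
    pixel_pitch: float  # arcmin / pixel
    wavelength: float  # nm
    pupil_diameter: float  # mm
    residual_defocus: float  # diopters

    @property
    def coords(self) -> np.ndarray:
        return _grid_coords(self.grid.shape[0], self.pixel_pitch)

    def volume(self) -> float:
        return float(self.grid.sum() * self.pixel_pitch**2)


@dataclass
class RetinalLightDistribution:
    """Unit-integral stimulus light profile on the retina.

    ``center`` is the delivery point in mosaic coordinates (arcmin); the
    grid itself is sampled on coordinates centred at zero, so absolute
    positions are ``coords + center``.
    """

    grid: np.ndarray
    pixel_pitch: float
    center: tuple[float, float]
    wavelength: float

    @property
    def coords(self) -> np.ndarray:
        return _grid_coords(self.grid.shape[0], self.pixel_pitch)

    def integral(self) -> float:
        return float(self.grid.sum() * self.pixel_pitch**2)


@dataclass
class ApertureMap:
    """One unit-volume Gaussian aperture per cone of a mosaic."""

    mosaic: ConeMosaic
    fwhm: float = DEFAULT_APERTURE_FWHM

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    def class_density(self, x: np.ndarray, y: np.ndarray, cls: str) -> np.ndarray:
        """Sum of the class's aperture Gaussians evaluated on a meshgrid.

        Only cones within 6 sigma of the grid's bounding box contribute;
        farther apertures are numerically zero.
        """
        pts = self.mosaic.positions_of(cls)
        out = np.zeros(np.broadcast(x, y).shape)
        if pts.shape[0] == 0:
            return out
        pad = 6.0 * self.sigma
        keep = (
            (pts[:, 0] >= x.min() - pad)
            & (pts[:, 0] <= x.max() + pad)
            & (pts[:, 1] >= y.min() - pad)
            & (pts[:, 1] <= y.max() + pad)
        )
        norm = 1.0 / (2.0 * np.pi * self.sigma**2)
        inv2s2 = 1.0 / (2.0 * self.sigma**2)
        for cx, cy in pts[keep]:
            out += norm * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) * inv2s2)
        return out


def diffraction_psf(
    wavelength: float,
    pupil_diameter: float = 6.5,
    defocus: float = 0.0,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    grid_size: int = 256,
    border_energy_tol: float = 1e-3,
) -> PointSpreadFunction:
    """Fourier-optics PSF of a circular pupil with quadratic defocus.

    Parameters are wavelength in nm, pupil diameter in mm, defocus in
    diopters, angular sampling in arcmin per pixel.  Raises
    :class:`ResolutionError` when the grid cannot contain the pupil or
    when a non-negligible fraction of PSF energy piles up at the grid
    border (the practical symptom of an under-sized grid).
    """
    if not 400.0 <= wavelength <= 900.0:
        raise InvalidParameterError("wavelength must lie in [400, 900] nm")
    if pupil_diameter <= 0:
        raise InvalidParameterError("pupil diameter must be > 0")
    if pixel_pitch <= 0 or grid_size < 16:
        raise InvalidParameterError("need pixel_pitch > 0 and grid_size >= 16")

    lam_m = wavelength * 1e-9
    dtheta = pixel_pitch / ARCMIN_PER_RAD  # rad / pixel in the image plane
    dx = lam_m / (grid_size * dtheta)  # pupil-plane sampling, m
    r_pupil = pupil_diameter * 1e-3 / 2.0
    xs = (np.arange(grid_size) - grid_size // 2) * dx
    if r_pupil > np.abs(xs).max():
        raise ResolutionError(
            "pupil does not fit the numerical aperture grid; increase "
            "grid_size or coarsen pixel_pitch"
        )
    xx, yy = np.meshgrid(xs, xs)
    r2 = xx**2 + yy**2
    pupil = (r2 <= r_pupil**2).astype(float)
    # quadratic wavefront: OPD = (D/2) r^2, meters
    opd = 0.5 * defocus * r2
    field = pupil * np.exp(2j * np.pi * opd / lam_m)
    psf = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field)))) ** 2

    border = psf[:2, :].sum() + psf[-2:, :].sum() + psf[2:-2, :2].sum() + psf[2:-2, -2:].sum()
    if border > border_energy_tol * psf.sum():
        raise ResolutionError(
            "PSF energy reaches the grid border (<99.9% captured); "
            "enlarge grid_size"
        )
    psf /= psf.sum() * pixel_pitch**2
    return PointSpreadFunction(
        grid=psf,
        pixel_pitch=pixel_pitch,
        wavelength=wavelength,
        pupil_diameter=pupil_diameter,
        residual_defocus=defocus,
    )


def delta_psf(pixel_pitch: float = DEFAULT_PIXEL_PITCH, grid_size: int = 64,
              wavelength: float = 543.0) -> PointSpreadFunction:
    """Idealized aberration-free delta-function PSF (testing / no-blur runs)."""
    g = np.zeros((grid_size, grid_size))
    g[grid_size // 2, grid_size // 2] = 1.0 / pixel_pitch**2
    return PointSpreadFunction(g, pixel_pitch, wavelength, float("inf"), 0.0)


def airy_first_minimum_arcmin(wavelength: float, pupil_diameter: float) -> float:
    """Angular radius 1.22 lambda / D of the first Airy minimum, arcmin."""
    return 1.22 * (wavelength * 1e-9) / (pupil_diameter * 1e-3) * ARCMIN_PER_RAD


def equivalent_width(psf: PointSpreadFunction) -> float:
    """Volume-equivalent width: volume / peak, arcmin^2 per unit height.

    A simple scalar that grows as aberrations spread the PSF.
    """
    return psf.volume() / float(psf.grid.max())


def retinal_light_distribution(
    stimulus_side: float,
    psf: PointSpreadFunction,
    delivery_center: tuple[float, float] = (0.0, 0.0),
) -> RetinalLightDistribution:
    """Unit-integral uniform square of side ``stimulus_side`` (arcmin)
    convolved with the PSF, delivered at ``delivery_center``.

    The square is rendered with exact area weighting (partial pixels at
    the edges), so the profile is correct even when the side is not an
    integer number of pixels.
    """
    if stimulus_side <= 0:
        raise InvalidParameterError("stimulus_side must be > 0")
    pitch = psf.pixel_pitch
    n = psf.grid.shape[0]
    c = _grid_coords(n, pitch)
    half = stimulus_side / 2.0
    # fractional coverage of each pixel column/row by the square
    cover = np.clip((np.minimum(c + pitch / 2, half) - np.maximum(c - pitch / 2, -half)) / pitch, 0.0, 1.0)
    square = np.outer(cover, cover) / stimulus_side**2
    # centred circular FFT convolution keeps the grid centre exactly at
    # index n//2 (a linear "same"-mode convolution is off by one pixel on
    # even grids); both supports are far from the border, so wraparound
    # is negligible
    grid = np.real(
        np.fft.fftshift(
            np.fft.ifft2(
                np.fft.fft2(np.fft.ifftshift(square)) * np.fft.fft2(np.fft.ifftshift(psf.grid))
            )
        )
    ) * pitch**2
    grid = np.clip(grid, 0.0, None)
    grid /= grid.sum() * pitch**2
    return RetinalLightDistribution(
        grid=grid,
        pixel_pitch=pitch,
        center=tuple(float(v) for v in delivery_center),
        wavelength=psf.wavelength,
    )


def build_aperture_map(mosaic: ConeMosaic, fwhm: float = DEFAULT_APERTURE_FWHM) -> ApertureMap:
    """Gaussian aperture map with the given FWHM (arcmin) for every cone."""
    if fwhm <= 0:
        raise InvalidParameterError("aperture fwhm must be > 0")
    return ApertureMap(mosaic=mosaic, fwhm=fwhm)
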