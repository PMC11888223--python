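"""Observer-specific cone spectral sensitivities in corneal quantal units.

The chain is the standard physiological-optics one: a lambda_max-
parameterized visual-pigment absorbance template (Govardovskii A1
nomogram) is converted to axial absorptance through the pigment's
effective axial optical density (specific density x outer-segment
length x unbleached fraction), then filtered by lens and macular
pigment densities.

The lens and macular spectral templates are smooth parametric stand-ins
for the published age-dependent tables (which the source formulae
tabulate rather than print in closed form); both are injectable, and at
the 543/680 nm analysis wavelengths pre-receptoral filtering is in any
case nearly negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import InvalidParameterError

#: default half-bleach constant, isomerizations / s
HALF_BLEACH_ISOM_PER_S = 10**6.4
#: documented troland -> isomerization-rate conversion (see methods note):
#: the troland-domain cone half-bleach constant 10^4.3 Td corresponds to
#: 10^6.4 isomerizations/s, i.e. 10^2.1 isomerizations/s per troland.
ISOM_PER_SEC_PER_TROLAND = 10**2.1

DEFAULT_WAVELENGTHS = np.arange(390.0, 831.0, 1.0)

#: common L-cone spectral-peak variants, nm
L_LAMBDA_MAX_PRESETS = (555.5, 558.9, 563.4)
DEFAULT_LAMBDA_MAX = {"L": 558.9, "M": 530.3, "S": 420.7}
#: photopigment specific density, 1/um (package default; field-standard value)
DEFAULT_SPECIFIC_DENSITY = 0.015


# ---------------------------------------------------------------------------
# pigment absorbance nomogram
# ---------------------------------------------------------------------------

def govardovskii_template(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment absorbance template, peak-normalized.

    Alpha band plus beta band, valid for lambda_max roughly 350-600 nm.
    """
    if not 350.0 <= lambda_max <= 600.0:
        raise InvalidParameterError("lambda_max outside template validity (350-600 nm)")
    lam = np.asarray(wavelengths, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lam_beta) / b_beta) ** 2))
    return np.clip(alpha + beta, 0.0, None)


# ---------------------------------------------------------------------------
# ocular media
# ---------------------------------------------------------------------------

def default_lens_template(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth lens optical-density template for a ~32-year standard eye.

    Exponential decline calibrated to the standard-observer lens density
    scale (~1.76 at 400 nm, ~0.06 at 550 nm, ~0 in the deep red).
    """
    lam = np.asarray(wavelengths, dtype=float)
    return 1.76 * np.exp(-(lam - 400.0) / 42.5)


def default_macular_template(wavelengths: np.ndarray) -> np.ndarray:
    """Normalized (unit-peak) macular pigment density template.

    Gaussian centred at 460 nm, truncated to zero beyond 550 nm where
    macular pigment does not absorb.
    """
    lam = np.asarray(wavelengths, dtype=float)
    t = np.exp(-(((lam - 460.0) / 38.0) ** 2))
    return np.where(lam > 550.0, 0.0, t)


def default_mpod_field_size_function(field_size_deg: np.ndarray) -> np.ndarray:
    """MPOD as a function of field size (deg): 0.485 * exp(-fs / 6.132)."""
    return 0.485 * np.exp(-np.asarray(field_size_deg, dtype=float) / 6.132)


def mpod_peak(e1: float, e2: float, D: Callable[[float], float]) -> float:
    """Peak macular pigment density between retinal eccentricities e1 < e2.

    Inverts the field-size-averaged density relation:

        MPOD_peak = -log10( (10^(-D(2 e2)) e2^2 - 10^(-D(2 e1)) e1^2)
                            / (e2^2 - e1^2) )

    where D(.) maps field size (deg, i.e. twice the eccentricity) to the
    field-averaged MPOD.  A negative result (possible with a non-physical
    D) is clipped to zero.
    """
    if not 0 < e1 < e2:
        raise InvalidParameterError("require 0 < e1 < e2")
    num = 10.0 ** (-float(D(2 * e2))) * e2**2 - 10.0 ** (-float(D(2 * e1))) * e1**2
    val = -np.log10(num / (e2**2 - e1**2))
    if val < 0:
        import warnings

        warnings.warn("mpod_peak evaluated negative; clipping to 0", stacklevel=2)
        return 0.0
    return float(val)


def unbleached_fraction(
    isomerization_rate: float, half_bleach: float = HALF_BLEACH_ISOM_PER_S
) -> float:
    """Steady-state fraction of unbleached photopigment.

    half_bleach / (half_bleach + rate); equals 0.5 when the background
    drives isomerizations at exactly the half-bleach constant.
    """
    if isomerization_rate < 0:
        raise InvalidParameterError("isomerization rate must be >= 0")
    return half_bleach / (half_bleach + isomerization_rate)


def background_isomerization_rate(
    luminance_cd_m2: float, pupil_diameter_mm: float = 6.5
) -> float:
    """Isomerization rate driven by a photopic background.

    Photometric chain: retinal illuminance in trolands = luminance x
    pupil area (mm^2); isomerizations/s = trolands x 10^2.1, the scale on
    which the troland-domain cone half-bleach constant (10^4.3 Td) maps
    onto 10^6.4 isomerizations/s.
    """
    if luminance_cd_m2 < 0 or pupil_diameter_mm <= 0:
        raise InvalidParameterError("luminance >= 0 and pupil > 0 required")
    trolands = luminance_cd_m2 * np.pi * (pupil_diameter_mm / 2.0) ** 2
    return trolands * ISOM_PER_SEC_PER_TROLAND


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class OcularMediaModel:
    """Lens + macular pigment filtering for one observer."""

    age: float = 32.0
    mpod_peak: float = 0.0
    lens_template: Callable[[np.ndarray], np.ndarray] = default_lens_template
    macular_template: Callable[[np.ndarray], np.ndarray] = default_macular_template
    lens_scale: float | None = None

    def lens_density(self, wavelengths: np.ndarray) -> np.ndarray:
        """Age-scaled lens optical density (linear 2%/year around age 32)."""
        scale = self.lens_scale
        if scale is None:
            scale = 1.0 + 0.02 * (self.age - 32.0)
        return np.clip(scale, 0.0, None) * self.lens_template(wavelengths)

    def macular_density(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.mpod_peak * self.macular_template(wavelengths)


@dataclass
class PigmentModel:
    """Photopigment parameters for the three cone classes."""

    lambda_max: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAMBDA_MAX))
    specific_density: float = DEFAULT_SPECIFIC_DENSITY  # 1/um
    outer_segment_length: float = 35.0  # um
    unbleached_fraction: float = 1.0
    template: Callable[[np.ndarray, float], np.ndarray] = govardovskii_template

    def __post_init__(self) -> None:
        if not 0.0 <= self.unbleached_fraction <= 1.0:
            raise InvalidParameterError("unbleached_fraction must lie in [0, 1]")
        if self.specific_density < 0 or self.outer_segment_length < 0:
            raise InvalidParameterError("densities and lengths must be >= 0")

    @property
    def axial_density_unbleached(self) -> float:
        return self.specific_density * self.outer_segment_length

    @property
    def axial_density_effective(self) -> float:
        return self.axial_density_unbleached * self.unbleached_fraction


@dataclass
class ConeFundamentals:
    """Corneal quantal spectral sensitivities per cone class."""

    wavelengths: np.ndarray
    sensitivity: dict[str, np.ndarray]

    def at(self, cls: str, wavelength: float) -> float:
        return float(np.interp(wavelength, self.wavelengths, self.sensitivity[cls]))

    def peak_normalized(self) -> "ConeFundamentals":
        return ConeFundamentals(
            wavelengths=self.wavelengths,
            sensitivity={c: s / s.max() if s.max() > 0 else s for c, s in self.sensitivity.items()},
        )


def build_fundamentals(
    media: OcularMediaModel,
    pigment: PigmentModel,
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
    classes: tuple[str, ...] = ("L", "M", "S"),
    peak_normalize: bool = False,
) -> ConeFundamentals:
    """Corneal quantal sensitivity per class:

        absorptance(lam) = 1 - 10^(-d_eff * template(lam; lambda_max))
        S(lam) = absorptance(lam) * 10^(-lens(lam) - macular(lam))
    """
    lam = np.asarray(wavelengths, dtype=float)
    media_trans = 10.0 ** (-(media.lens_density(lam) + media.macular_density(lam)))
    out = {}
    for cls in classes:
        absorbance = pigment.template(lam, pigment.lambda_max[cls])
        absorptance = 1.0 - 10.0 ** (-pigment.axial_density_effective * absorbance)
        out[cls] = absorptance * media_trans
    fund = ConeFundamentals(wavelengths=lam, sensitivity=out)
    return fund.peak_normalized() if peak_normalize else fund


# ---------------------------------------------------------------------------
# primary excitations
# ---------------------------------------------------------------------------

@dataclass
class ExcitationTable:
    """Cone excitations per corneal quantum of each stimulus primary."""

    L_680: float
    M_680: float
    L_543: float
    M_543: float


def primary_excitation(
    fundamentals: ConeFundamentals,
    cls: str,
    center: float,
    half_bandwidth: float = 0.0,
) -> float:
    """Band-weighted mean sensitivity over a Gaussian primary spectrum.

    ``half_bandwidth`` is the half-width at half maximum (the +/- value
    quoted for the stimulus channels); 0 degenerates to the sensitivity
    at the centre wavelength.
    """
    lam = fundamentals.wavelengths
    if not lam[0] <= center <= lam[-1]:
        raise InvalidParameterError("primary centre outside the wavelength grid")
    s = fundamentals.sensitivity[cls]
    if half_bandwidth <= 0:
        return float(np.interp(center, lam, s))
    sigma = 2.0 * half_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if center - 5 * sigma < lam[0] or center + 5 * sigma > lam[-1]:
        raise InvalidParameterError("primary band extends outside the wavelength grid")
    lam_fine = np.linspace(center - 5 * sigma, center + 5 * sigma, 2001)
    s_fine = np.interp(lam_fine, lam, s)
    w = np.exp(-((lam_fine - center) ** 2) / (2.0 * sigma**2))
    return float(np.trapezoid(w * s_fine, lam_fine) / np.trapezoid(w, lam_fine))


def excitation_table(
    fundamentals: ConeFundamentals,
    half_bandwidth_680: float = 14.9,
    half_bandwidth_543: float = 13.5,
) -> ExcitationTable:
    """L/M excitations per corneal quantum of the 680 and 543 nm primaries."""
    return ExcitationTable(
        L_680=primary_excitation(fundamentals, "L", 680.0, half_bandwidth_680),
        M_680=primary_excitation(fundamentals, "M", 680.0, half_bandwidth_680),
        L_543=primary_excitation(fundamentals, "L", 543.0, half_bandwidth_543),
        M_543=primary_excitation(fundamentals, "M", 543.0, half_bandwidth_543),
    )
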