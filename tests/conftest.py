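"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings
from scipy.special import expit

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")

import smallspot as ss
from smallspot.pipeline import fit_study_thresholds
from smallspot.synthesize import SyntheticStudyConfig, synthesize_study


@pytest.fixture(scope="session")
def hex_mosaic():
    """Noise-free 1000-cone hexagonal mosaic, spacing 1.2 arcmin."""
    return ss.generate_mosaic(
        1000, spacing=1.2, jitter_sd=0.0, fraction_L_of_LM=0.6, fraction_S=0.05, seed=11
    )


@pytest.fixture(scope="session")
def jittered_mosaic():
    return ss.generate_mosaic(
        1000, spacing=1.1, jitter_sd=0.11, fraction_L_of_LM=0.595, fraction_S=0.05, seed=2
    )


@pytest.fixture(scope="session")
def psf_543():
    return ss.diffraction_psf(543.0, 6.5, 0.05, pixel_pitch=0.11, grid_size=192)


@pytest.fixture(scope="session")
def light_543(psf_543):
    return ss.retinal_light_distribution(2.25, psf_543)


@pytest.fixture(scope="session")
def default_study():
    """Full synthetic study at the default conditions, master seed 0."""
    return synthesize_study(SyntheticStudyConfig(master_seed=0))


@pytest.fixture(scope="session")
def default_measurements(default_study):
    measurements, included, inclusion = fit_study_thresholds(default_study)
    return measurements, included, inclusion


def simulate_glmm_trials(
    n: int,
    seed: int,
    beta0: float = -2.0,
    beta1: float = float(np.log(2.94)),
    beta2: float = float(np.log(5.51)),
    beta3: float = 0.0,
    sigma_subject: float = 0.3,
    sigma_wavelength: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Bernoulli trials from the color-naming logistic model: returns
    (y, fixed-effects design with intercept, grouping factors)."""
    rng = np.random.default_rng(seed)
    subj = rng.integers(0, 2, n)
    wav = rng.integers(0, 2, n)
    log2i = rng.uniform(-1.0, 4.0, n)
    het = rng.uniform(0.0, 1.0, n)
    sdist = rng.uniform(0.0, 3.0, n)
    bs = rng.normal(0.0, sigma_subject, 2)
    bw = rng.normal(0.0, sigma_wavelength, 2)
    eta = beta0 + beta1 * log2i + beta2 * het + beta3 * sdist + bs[subj] + bw[wav]
    y = (rng.random(n) < expit(eta)).astype(float)
    X = pd.DataFrame(
        {
            "intercept": np.ones(n),
            "log2_intensity": log2i,
            "heterogeneity": het,
            "s_cone_distance": sdist,
        }
    )
    return y, X, {"subject": subj, "wavelength": wav}
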