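"""Color-naming analysis of seen trials.

A seen flash is an "expected" color response when it was called green at
543 nm or red at 680 nm (matching the large-field appearance of those
wavelengths).  The analyses here quantify how the expected-response rate
depends on stimulus intensity (as a threshold multiple), local L/M
heterogeneity, and distance to the nearest S cone: binned response
matrices, a heterogeneity-tertile breakdown, and the logistic
mixed-effects model

    logit(pi) = b0 + b1 log2(intensity) + b2 heterogeneity
                + b3 s_cone_distance + u_subject + u_wavelength
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .glmm import MixedLogitResult, fit_logistic_fixed, fit_logistic_mixed
from .glmm import likelihood_ratio_test as _lr_test

EXPECTED_RESPONSE = {543.0: "green", 680.0: "red"}

#: fixed-effect design columns of the color GLMM, in order
GLMM_PREDICTORS = ["log2_intensity", "heterogeneity", "s_cone_distance"]


def expected_response_indicator(
    wavelength: float | np.ndarray, color_response: str | np.ndarray
) -> bool | np.ndarray:
    """True iff the response matches the wavelength's expected color.

    Raises for not-seen trials: expectation is defined only conditional
    on detection.
    """
    wl = np.asarray(wavelength, dtype=float)
    resp = np.asarray(color_response, dtype="U12")
    if np.any(resp == "not_seen"):
        raise InvalidInputError("expected-response coding applies to seen trials only")
    expect = np.where(np.isclose(wl, 543.0), "green", np.where(np.isclose(wl, 680.0), "red", "?"))
    if np.any(expect == "?"):
        raise InvalidInputError("wavelength must be 543 or 680 nm")
    out = resp == expect
    return bool(out) if out.ndim == 0 else out


def _require_seen(trials: pd.DataFrame) -> pd.DataFrame:
    seen = trials[trials["seen"].astype(bool)].copy()
    if len(seen) == 0:
        raise InvalidInputError("no seen trials")
    seen["expected"] = expected_response_indicator(
        seen["wavelength"].to_numpy(), seen["color_response"].to_numpy()
    )
    return seen


@dataclass
class ResponseMatrix:
    """Expected-response rate binned by intensity multiple and proportion L.

    Cells with fewer than ``min_n`` trials are flagged ``suppressed``;
    empty cells additionally carry rate NaN, so a true 0% cell and an
    empty cell remain distinguishable.
    """

    intensity_edges: np.ndarray
    pL_edges: np.ndarray
    rate: np.ndarray  # (n_intensity_bins, n_pL_bins)
    n: np.ndarray
    suppressed: np.ndarray
    min_n: int


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed/right-open bins, last bin closed; -1 outside range."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise InvalidInputError("bin edges must be strictly increasing")
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.where(np.isclose(values, edges[-1]), len(edges) - 2, idx)
    idx = np.where((values < edges[0]) | (values > edges[-1]), -1, idx)
    return idx.astype(int)


def build_response_matrix(
    trials: pd.DataFrame,
    intensity_edges: np.ndarray,
    pL_edges: np.ndarray,
    min_n: int = 10,
) -> ResponseMatrix:
    """Per-cell expected-response rate over seen trials."""
    seen = _require_seen(trials)
    ii = _bin_index(seen["intensity_multiple"].to_numpy(dtype=float), intensity_edges)
    jj = _bin_index(seen["proportion_L"].to_numpy(dtype=float), pL_edges)
    ni, nj = len(intensity_edges) - 1, len(pL_edges) - 1
    n = np.zeros((ni, nj), dtype=int)
    k = np.zeros((ni, nj), dtype=float)
    ok = (ii >= 0) & (jj >= 0)
    np.add.at(n, (ii[ok], jj[ok]), 1)
    np.add.at(k, (ii[ok], jj[ok]), seen["expected"].to_numpy(dtype=float)[ok])
    with np.errstate(invalid="ignore"):
        rate = np.where(n > 0, k / np.where(n > 0, n, 1), np.nan)
    return ResponseMatrix(
        intensity_edges=np.asarray(intensity_edges, float),
        pL_edges=np.asarray(pL_edges, float),
        rate=rate,
        n=n,
        suppressed=n < min_n,
        min_n=min_n,
    )


def tertile_analysis(
    trials: pd.DataFrame,
    intensity_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expected-response rate by heterogeneity tertile x intensity bin.

    Tertile edges are the empirical 1/3 and 2/3 quantiles of per-trial
    heterogeneity over seen trials (ties at an edge go to the lower
    tertile).  Returns one row per (tertile, intensity bin) with the
    rate, trial count, and median intensity multiple (the natural
    x-position for plotting).
    """
    seen = _require_seen(trials)
    if len(seen) < 3:
        raise InvalidInputError("tertile analysis needs at least 3 seen trials")
    het = seen["heterogeneity"].to_numpy(dtype=float)
    q1, q2 = np.quantile(het, [1 / 3, 2 / 3])
    if np.unique(het).size < 3 or q1 == q2:
        warnings.warn("degenerate heterogeneity tertiles; using a single group", stacklevel=2)
        tert = np.zeros(len(seen), dtype=int)
    else:
        tert = np.where(het <= q1, 0, np.where(het <= q2, 1, 2))
    if intensity_edges is None:
        im = seen["intensity_multiple"].to_numpy(dtype=float)
        intensity_edges = np.quantile(im, np.linspace(0, 1, 6))
        intensity_edges[-1] += 1e-9
        intensity_edges = np.unique(intensity_edges)
    ib = _bin_index(seen["intensity_multiple"].to_numpy(dtype=float), intensity_edges)
    seen = seen.assign(tertile=tert, intensity_bin=ib)
    seen = seen[seen["intensity_bin"] >= 0]
    rows = []
    for (t, b), g in seen.groupby(["tertile", "intensity_bin"]):
        rows.append(
            {
                "tertile": int(t),
                "intensity_bin": int(b),
                "rate": float(g["expected"].mean()),
                "n": int(len(g)),
                "median_intensity": float(g["intensity_multiple"].median()),
            }
        )
    return pd.DataFrame(rows).sort_values(["tertile", "intensity_bin"]).reset_index(drop=True)


@dataclass
class ColorModelFit:
    """Color-naming GLMM fit plus the reporting the analysis needs."""

    result: MixedLogitResult
    odds_factors: pd.DataFrame
    n_trials: int

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def adjusted_r2(self) -> float:
        return self.result.pseudo_r2_adjusted


def _design(seen: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(seen))})
    for name in predictors:
        if name == "log2_intensity":
            X[name] = np.log2(seen["intensity_multiple"].to_numpy(dtype=float))
        else:
            X[name] = seen[name].to_numpy(dtype=float)
    return X


def fit_color_glmm(
    trials: pd.DataFrame,
    predictors: list[str] | None = None,
    allow_fallback: bool = True,
) -> ColorModelFit:
    """Fit the expected-color-response GLMM on seen trials.

    Random intercepts for subject and wavelength; fixed effects log2
    intensity multiple, heterogeneity, and S-cone distance (cone-spacing
    units).  Odds factors are per intensity doubling, per unit
    heterogeneity, and per cone spacing of S distance respectively.
    """
    predictors = GLMM_PREDICTORS if predictors is None else predictors
    seen = _require_seen(trials)
    if seen["intensity_multiple"].min() <= 0:
        raise InvalidInputError("intensity multiples must be positive for log2 transform")
    X = _design(seen, predictors)
    groups = {
        "subject": seen["subject_id"].to_numpy(),
        "wavelength": seen["wavelength"].to_numpy(),
    }
    if seen["subject_id"].nunique() < 2 or seen["wavelength"].nunique() < 2:
        raise InvalidInputError("need >= 2 subjects and >= 2 wavelengths for random intercepts")
    res = fit_logistic_mixed(seen["expected"].to_numpy(dtype=float), X, groups,
                             allow_fallback=allow_fallback)
    return ColorModelFit(result=res, odds_factors=res.odds_factors(), n_trials=len(seen))


def fit_color_fixed(trials: pd.DataFrame, predictors: list[str] | None = None) -> ColorModelFit:
    """Fixed-effects-only companion fit (subject/wavelength as fixed dummies),
    used to check that the shared coefficients agree with the mixed fit."""
    predictors = GLMM_PREDICTORS if predictors is None else predictors
    seen = _require_seen(trials)
    X = _design(seen, predictors)
    for name, col in (("subject", "subject_id"), ("wavelength", "wavelength")):
        d = pd.get_dummies(seen[col], prefix=name, drop_first=True)
        for c in d.columns:
            X[str(c)] = d[c].to_numpy(dtype=float)
    res = fit_logistic_fixed(seen["expected"].to_numpy(dtype=float), X)
    return ColorModelFit(result=res, odds_factors=res.odds_factors(), n_trials=len(seen))


def likelihood_ratio_test(full: ColorModelFit, reduced: ColorModelFit):
    """LR test between nested color-model fits: (lr, delta_df, delta_aic, p)."""
    return _lr_test(full.result, reduced.result)
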