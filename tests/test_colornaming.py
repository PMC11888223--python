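"""Expected-response coding, response matrices, tertiles, and the color GLMM."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import smallspot as ss
from smallspot.colornaming import build_response_matrix, tertile_analysis
from smallspot.exceptions import InvalidInputError


class TestExpectedResponseIndicator:
    @pytest.mark.parametrize(
        "wl,resp,expected",
        [
            (543.0, "green", True),
            (680.0, "red", True),
            (680.0, "achromatic", False),
            (543.0, "red", False),
            (680.0, "green", False),
        ],
    )
    def test_coding(self, wl, resp, expected):
        assert ss.expected_response_indicator(wl, resp) is expected

    def test_not_seen_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.expected_response_indicator(543.0, "not_seen")

    def test_unknown_wavelength_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.expected_response_indicator(600.0, "red")


def _trials(intensity, pL, expected, wavelength=680.0, subject="S1"):
    n = len(intensity)
    resp = np.where(np.asarray(expected, bool), "red", "achromatic")
    return pd.DataFrame(
        {
            "subject_id": subject,
            "wavelength": wavelength,
            "intensity_multiple": intensity,
            "proportion_L": pL,
            "heterogeneity": 1 - np.abs(np.asarray(pL) - 0.5) / 0.5,
            "s_cone_distance": 1.0,
            "seen": True,
            "color_response": resp,
        }
    )


class TestResponseMatrix:
    def test_single_trial_suppressed(self):
        t = _trials([1.5], [0.55], [True])
        m = build_response_matrix(t, [1.0, 2.0], [0.5, 0.6], min_n=10)
        assert m.rate[0, 0] == 1.0
        assert m.suppressed[0, 0]

    def test_empty_cell_distinct_from_zero_rate(self):
        t = _trials([1.5, 1.5], [0.55, 0.55], [False, False])
        m = build_response_matrix(t, [1.0, 2.0, 3.0], [0.5, 0.6], min_n=1)
        assert m.rate[0, 0] == 0.0 and not np.isnan(m.rate[0, 0])
        assert np.isnan(m.rate[1, 0]) and m.n[1, 0] == 0

    def test_binomial_rates_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        t = _trials(
            rng.uniform(1, 3, n), rng.uniform(0.0, 1.0, n), rng.random(n) < 0.5
        )
        m = build_response_matrix(t, [1.0, 2.0, 3.0], [0.0, 0.5, 1.0], min_n=10)
        assert np.all(~m.suppressed)
        assert np.allclose(m.rate, 0.5, atol=4 * np.sqrt(0.25 / m.n.min()))

    def test_non_monotone_edges(self):
        t = _trials([1.5], [0.55], [True])
        with pytest.raises(InvalidInputError):
            build_response_matrix(t, [2.0, 1.0], [0, 1])

    def test_rate_invariant_to_shuffling(self):
        rng = np.random.default_rng(1)
        n = 500
        t = _trials(rng.uniform(1, 3, n), rng.uniform(0, 1, n), rng.random(n) < 0.3)
        a = build_response_matrix(t, [1.0, 2.0, 3.0], [0.0, 0.5, 1.0])
        b = build_response_matrix(
            t.sample(frac=1.0, random_state=2), [1.0, 2.0, 3.0], [0.0, 0.5, 1.0]
        )
        np.testing.assert_array_equal(a.n, b.n)
        np.testing.assert_allclose(a.rate, b.rate)


class TestTertileAnalysis:
    def test_degenerate_heterogeneity_single_group(self):
        t = _trials([1.0, 2.0, 3.0], [0.5] * 3, [True, False, True])
        with pytest.warns(UserWarning, match="degenerate"):
            out = tertile_analysis(t, intensity_edges=[0.5, 5.0])
        assert set(out["tertile"]) == {0}

    def test_monotone_effect_orders_tertiles(self):
        rng = np.random.default_rng(2)
        n = 9000
        pL = rng.uniform(0, 1, n)
        het = 1 - np.abs(pL - 0.5) / 0.5
        intensity = rng.uniform(1.0, 4.0, n)
        p = expit(-2.0 + 3.0 * het)
        t = _trials(intensity, pL, rng.random(n) < p)
        out = tertile_analysis(t, intensity_edges=[1.0, 2.0, 3.0, 4.0])
        piv = out.pivot(index="intensity_bin", columns="tertile", values="rate")
        for _, row in piv.iterrows():
            assert row[0] < row[1] < row[2]

    def test_balanced_counts_for_divisible_n(self):
        n = 9
        t = _trials(np.full(n, 1.5), np.linspace(0.05, 0.45, n), [True] * n)
        out = tertile_analysis(t, intensity_edges=[1.0, 2.0])
        counts = out.groupby("tertile")["n"].sum()
        assert counts.max() - counts.min() <= 1

    def test_median_intensity_reported(self):
        t = _trials([1.0, 2.0, 3.0, 4.0], [0.1, 0.4, 0.6, 0.9], [True] * 4)
        out = tertile_analysis(t, intensity_edges=[0.5, 5.0])
        assert (out["median_intensity"] >= 1.0).all()

    def test_too_few_trials(self):
        with pytest.raises(InvalidInputError):
            tertile_analysis(_trials([1.0], [0.5], [True]))


class TestColorGlmmOnTrials:
    def _study_trials(self, n=6000, seed=0, beta2=np.log(5.51)):
        rng = np.random.default_rng(seed)
        subj = np.where(rng.random(n) < 0.5, "A", "B")
        wl = np.where(rng.random(n) < 0.5, 543.0, 680.0)
        im = 2.0 ** rng.uniform(-1, 4, n)
        het = rng.uniform(0, 1, n)
        sdist = rng.uniform(0, 3, n)
        b_s = {"A": -0.2, "B": 0.2}
        b_w = {543.0: -0.8, 680.0: 0.8}
        eta = (
            -2.0
            + np.log(2.94) * np.log2(im)
            + beta2 * het
            + np.array([b_s[s] for s in subj])
            + np.array([b_w[w] for w in wl])
        )
        expected = rng.random(n) < expit(eta)
        resp = np.where(
            expected, np.where(wl == 543.0, "green", "red"), "achromatic"
        )
        return pd.DataFrame(
            {
                "subject_id": subj,
                "wavelength": wl,
                "intensity_multiple": im,
                "proportion_L": het * 0.5,  # placeholder; analysis uses heterogeneity
                "heterogeneity": het,
                "s_cone_distance": sdist,
                "seen": True,
                "color_response": resp,
            }
        )

    def test_recovers_generating_odds_factors(self):
        fit = ss.fit_color_glmm(self._study_trials())
        of = fit.odds_factors
        assert of.loc["log2_intensity", "lower"] < 2.94 < of.loc["log2_intensity", "upper"]
        assert of.loc["heterogeneity", "lower"] < 5.51 < of.loc["heterogeneity", "upper"]
        assert of.loc["s_cone_distance", "lower"] < 1.0 < of.loc["s_cone_distance", "upper"]

    def test_lr_test_flags_heterogeneity(self):
        trials = self._study_trials()
        full = ss.fit_color_glmm(trials)
        reduced = ss.fit_color_glmm(trials, predictors=["log2_intensity", "s_cone_distance"])
        lr, ddf, daic, p = ss.likelihood_ratio_test(full, reduced)
        assert ddf == 1 and p < 1e-6 and daic < 0

    def test_requires_two_subjects_and_wavelengths(self):
        t = self._study_trials(n=500)
        t["subject_id"] = "A"
        with pytest.raises(InvalidInputError):
            ss.fit_color_glmm(t)
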