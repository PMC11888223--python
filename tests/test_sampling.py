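"""Aperture-weighted cone sampling, proportion L, heterogeneity, and the
Monte Carlo site-selection null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smallspot as ss
from smallspot.exceptions import (
    GeometryError,
    InvalidInputError,
    InvalidParameterError,
)
from smallspot.mosaic import ConeMosaic
from smallspot.optics import delta_psf
from smallspot.sampling import (
    ConeCountKernel,
    SamplingResult,
    monte_carlo_sampling_null,
    proportion_L_at_centers,
)


class TestHeterogeneity:
    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.5)])
    def test_values(self, p, expected):
        assert ss.heterogeneity(p) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, p):
        h = ss.heterogeneity(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(ss.heterogeneity(1.0 - p), abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_domain(self, p):
        with pytest.raises(InvalidParameterError):
            ss.heterogeneity(p)


class TestProportionLWithRange:
    def test_closed_forms(self):
        r = ss.proportion_L_with_range({"L": 2.0, "M": 2.0, "U": 0.0})
        assert r.proportion_L == 0.5 and r.p_L_range == (0.5, 0.5)
        r = ss.proportion_L_with_range({"L": 3.0, "M": 1.0, "U": 1.0})
        assert r.proportion_L == pytest.approx(0.75)
        assert r.p_L_range[0] == pytest.approx(0.6)
        assert r.p_L_range[1] == pytest.approx(0.8)

    @given(
        st.floats(0.01, 10.0), st.floats(0.01, 10.0), st.floats(0.0, 10.0)
    )
    @settings(max_examples=200, deadline=None)
    def test_range_brackets_estimate(self, L, M, U):
        r = ss.proportion_L_with_range({"L": L, "M": M, "U": U})
        lo, hi = r.p_L_range
        assert lo <= r.proportion_L + 1e-12
        assert r.proportion_L <= hi / (1 - 1e-12) + 1e-12 or r.proportion_L <= hi + 1e-12

    def test_undefined_ratio(self):
        with pytest.raises(InvalidInputError):
            ss.proportion_L_with_range({"L": 0.0, "M": 0.0, "U": 1.0})


class TestTrialAveragedProportionL:
    def test_examples(self):
        assert ss.trial_averaged_proportion_L([0.5, 0.5]) == 0.5
        assert ss.trial_averaged_proportion_L([0.4, 0.6, 0.8]) == pytest.approx(0.6)

    def test_mean_within_bounds_and_accepts_results(self):
        vals = [0.31, 0.62, 0.44]
        results = [
            SamplingResult({"L": v, "M": 1 - v}, v, (v, v), 1.0, ss.heterogeneity(v))
            for v in vals
        ]
        m = ss.trial_averaged_proportion_L(results)
        assert min(vals) <= m <= max(vals)

    def test_empty(self):
        with pytest.raises(InvalidInputError):
            ss.trial_averaged_proportion_L([])


def _toy_mosaic(positions, classes):
    return ConeMosaic(np.asarray(positions, float), np.asarray(classes), (40, 40))


class TestEffectiveConeCounts:
    def test_all_L_patch(self):
        m = ss.generate_mosaic(400, spacing=1.0, jitter_sd=0.0, fraction_L_of_LM=1.0,
                               fraction_S=0.0, seed=1)
        light = ss.retinal_light_distribution(2.25, delta_psf(0.1, 64))
        counts = ss.effective_cone_counts(light, ss.build_aperture_map(m))
        assert counts["M"] == 0.0 and counts["L"] > 0
        assert ss.proportion_L_with_range(counts).proportion_L == 1.0

    def test_mirror_symmetry_gives_half(self):
        m = _toy_mosaic([[-0.8, 0.0], [0.8, 0.0]], ["L", "M"])
        light = ss.retinal_light_distribution(2.25, delta_psf(0.05, 128))
        counts = ss.effective_cone_counts(light, ss.build_aperture_map(m))
        p = ss.proportion_L_with_range(counts).proportion_L
        assert p == pytest.approx(0.5, abs=1e-6)

    def test_quadrature_oracle_toy_layout(self, psf_543):
        # brute-force integration at 4x finer pitch as the oracle
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1.5, 1.5, size=(3, 2))
        m = _toy_mosaic(pts, ["L", "M", "S"])
        coarse = ss.effective_cone_counts(
            ss.retinal_light_distribution(2.25, psf_543), ss.build_aperture_map(m)
        )
        psf_fine = ss.diffraction_psf(543.0, 6.5, 0.05, 0.11 / 4, 768)
        fine = ss.effective_cone_counts(
            ss.retinal_light_distribution(2.25, psf_fine), ss.build_aperture_map(m)
        )
        for cls in ("L", "M", "S"):
            assert coarse[cls] == pytest.approx(fine[cls], abs=1e-3)

    def test_additive_over_disjoint_subsets(self, psf_543):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-2, 2, size=(6, 2))
        light = ss.retinal_light_distribution(2.25, psf_543)
        all_L = ss.effective_cone_counts(
            light, ss.build_aperture_map(_toy_mosaic(pts, ["L"] * 6))
        )["L"]
        part1 = ss.effective_cone_counts(
            light, ss.build_aperture_map(_toy_mosaic(pts[:3], ["L"] * 3))
        )["L"]
        part2 = ss.effective_cone_counts(
            light, ss.build_aperture_map(_toy_mosaic(pts[3:], ["L"] * 3))
        )["L"]
        assert all_L == pytest.approx(part1 + part2, rel=1e-9)

    def test_proportion_independent_of_normalization(self, psf_543, jittered_mosaic):
        light = ss.retinal_light_distribution(2.25, psf_543, (1.0, -2.0))
        ap = ss.build_aperture_map(jittered_mosaic)
        a = ss.effective_cone_counts(light, ap)
        b = ss.effective_cone_counts(light, ap, normalization="peak")
        pa = a["L"] / (a["L"] + a["M"])
        pb = b["L"] / (b["L"] + b["M"])
        assert pa == pytest.approx(pb, rel=1e-9)

    def test_empty_mosaic(self, light_543):
        empty = ConeMosaic(np.empty((0, 2)), np.empty(0, dtype="U1"), (10, 10))
        with pytest.raises(InvalidInputError):
            ss.effective_cone_counts(light_543, ss.build_aperture_map(empty))


class TestMonteCarloNull:
    def test_single_iteration_sd_zero(self, jittered_mosaic, light_543):
        null = monte_carlo_sampling_null(jittered_mosaic, light_543, 10, 1, seed=0)
        assert np.all(null.sd_counts == 0.0)

    def test_counts_conserved(self, jittered_mosaic, light_543):
        null = monte_carlo_sampling_null(jittered_mosaic, light_543, 13, 200, seed=0)
        assert null.mean_counts.sum() == pytest.approx(13.0, abs=1e-9)

    def test_all_L_mosaic_top_bin(self, light_543):
        m = ss.generate_mosaic(900, spacing=1.0, jitter_sd=0.05, fraction_L_of_LM=1.0,
                               fraction_S=0.0, seed=2)
        null = monte_carlo_sampling_null(m, light_543, 8, 50, seed=0)
        assert null.mean_counts[-1] == pytest.approx(8.0)
        assert np.all(null.mean_counts[:-1] == 0.0)

    def test_deterministic(self, jittered_mosaic, light_543):
        a = monte_carlo_sampling_null(jittered_mosaic, light_543, 9, 50, seed=7)
        b = monte_carlo_sampling_null(jittered_mosaic, light_543, 9, 50, seed=7)
        np.testing.assert_array_equal(a.mean_counts, b.mean_counts)
        np.testing.assert_array_equal(a.sd_counts, b.sd_counts)

    def test_patch_too_small(self, light_543):
        m = ss.generate_mosaic(7, spacing=1.0, seed=1)
        with pytest.raises(GeometryError):
            monte_carlo_sampling_null(m, light_543, 5, 5, seed=0)

    def test_kernel_matches_full_grid(self, jittered_mosaic, psf_543, light_543):
        kernel = ConeCountKernel(light_543, ss.build_aperture_map(jittered_mosaic))
        rng = np.random.default_rng(0)
        centers = rng.uniform(-8, 8, size=(6, 2))
        fast = proportion_L_at_centers(jittered_mosaic, kernel, centers)
        for c, pf in zip(centers, fast):
            light = ss.retinal_light_distribution(2.25, psf_543, tuple(c))
            counts = ss.effective_cone_counts(light, ss.build_aperture_map(jittered_mosaic))
            full = counts["L"] / (counts["L"] + counts["M"])
            # the truncated-kernel fast path trades ~1e-2 accuracy in p_L
            # for the speed the 10^4-iteration Monte Carlo needs; that is
            # far below the 1/8 bin width it feeds
            assert pf == pytest.approx(full, abs=1e-2)
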