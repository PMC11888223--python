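"""Mosaic generation, Delaunay cone spacing, and S-cone distance."""

import numpy as np
import pytest
from scipy.stats import chisquare

import smallspot as ss
from smallspot.exceptions import GeometryError, InvalidParameterError, MissingClassError
from smallspot.mosaic import ConeMosaic, read_mosaic, write_mosaic


class TestGenerateMosaic:
    def test_degenerate_all_L_hex(self):
        m = ss.generate_mosaic(7, spacing=1.0, jitter_sd=0.0, fraction_L_of_LM=1.0,
                               fraction_S=0.0, seed=1)
        assert m.n == 7
        assert set(m.classes) == {"L"}
        # hexagonal geometry: six sites at unit distance from the centre
        d = np.sort(np.hypot(*m.positions.T))
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d[1:], 1.0, atol=1e-9)

    def test_fraction_within_binomial_error(self):
        m = ss.generate_mosaic(1000, fraction_L_of_LM=0.595, fraction_S=0.05, seed=2)
        c = m.class_counts()
        n_lm = c["L"] + c["M"]
        se = np.sqrt(0.595 * 0.405 / n_lm)
        assert abs(m.proportion_L - 0.595) < 4 * se

    def test_same_seed_identical(self, tmp_path):
        a = ss.generate_mosaic(300, seed=5)
        b = ss.generate_mosaic(300, seed=5)
        write_mosaic(a, tmp_path / "a.tsv")
        write_mosaic(b, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    @pytest.mark.parametrize("kwargs", [dict(n_cones=0), dict(spacing=0.0),
                                        dict(spacing=-1.0), dict(fraction_S=1.5)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ss.generate_mosaic(**{"n_cones": 10, **kwargs})

    def test_class_counts_multinomial(self):
        # chi-square of observed counts against the requested fractions
        fU, fS, fL = 0.03, 0.05, 0.6
        m = ss.generate_mosaic(10_000, fraction_L_of_LM=fL, fraction_S=fS,
                               fraction_unclassified=fU, seed=17)
        c = m.class_counts()
        pU = fU
        pS = (1 - fU) * fS
        pL = (1 - fU) * (1 - fS) * fL
        pM = (1 - fU) * (1 - fS) * (1 - fL)
        obs = [c["U"], c["S"], c["L"], c["M"]]
        exp = np.array([pU, pS, pL, pM]) * m.n
        stat, p = chisquare(obs, exp)
        assert p > 1e-4

    def test_positions_inside_extent(self, jittered_mosaic):
        hw, hh = np.array(jittered_mosaic.patch_extent) / 2
        x, y = jittered_mosaic.positions.T
        assert np.abs(x).max() <= hw and np.abs(y).max() <= hh

    def test_clumping_preserves_classes_and_increases_patchiness(self):
        base = ss.generate_mosaic(2000, fraction_L_of_LM=0.5, fraction_S=0.0, seed=3)
        clumped = ss.generate_mosaic(2000, fraction_L_of_LM=0.5, fraction_S=0.0,
                                     seed=3, clumping=4)
        assert set(np.unique(clumped.classes)) <= {"L", "M"}
        # same-class nearest-neighbour rate should rise under clumping
        def same_rate(m):
            _, idx = m.tree().query(m.positions, k=2)
            return np.mean(m.classes[idx[:, 0]] == m.classes[idx[:, 1]])
        assert same_rate(clumped) > same_rate(base)


class TestConeSpacing:
    def test_hex_lattice_identity(self, hex_mosaic):
        # all Delaunay edges enter the mean, so sliver triangles along the
        # jagged patch boundary bias it slightly high of the lattice pitch;
        # on a 1000-cone interior-dominated patch that bias stays below 5%
        assert ss.cone_spacing(hex_mosaic) == pytest.approx(1.2, rel=0.05)
        assert ss.cone_spacing(hex_mosaic) >= 1.2

    def test_equilateral_triangle(self):
        m = ConeMosaic(
            positions=np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]),
            classes=np.array(["L", "M", "L"]),
            patch_extent=(4.0, 4.0),
        )
        assert ss.cone_spacing(m) == pytest.approx(1.0, abs=1e-12)

    def test_jittered_lattice_matches_brute_force(self):
        # independent oracle on a 100-cone instance: rebuild the edge set
        # from scratch by pairwise distances over Delaunay simplices
        from scipy.spatial import Delaunay

        m = ss.generate_mosaic(100, spacing=1.0, jitter_sd=0.05, seed=4)
        tri = Delaunay(m.positions)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    edges.add(tuple(sorted((simplex[a], simplex[b]))))
        lengths = [
            float(np.hypot(*(m.positions[i] - m.positions[j]))) for i, j in edges
        ]
        assert ss.cone_spacing(m) == pytest.approx(np.mean(lengths), rel=1e-12)

    def test_jittered_lattice_near_pitch(self):
        m = ss.generate_mosaic(1000, spacing=1.0, jitter_sd=0.05, seed=4)
        assert ss.cone_spacing(m) == pytest.approx(1.0, rel=0.05)

    def test_rigid_motion_invariance(self, jittered_mosaic):
        s0 = ss.cone_spacing(jittered_mosaic)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = ConeMosaic(
            positions=jittered_mosaic.positions @ R.T + [3.0, -2.0],
            classes=jittered_mosaic.classes,
            patch_extent=(200.0, 200.0),
        )
        assert ss.cone_spacing(moved) == pytest.approx(s0, rel=1e-9)

    def test_too_few_or_collinear(self):
        m2 = ConeMosaic(np.array([[0, 0], [1, 0]]), np.array(["L", "M"]), (4, 4))
        with pytest.raises(GeometryError):
            ss.cone_spacing(m2)
        coll = ConeMosaic(
            np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]),
            np.array(["L", "M", "L", "M"]),
            (8, 8),
        )
        with pytest.raises(GeometryError):
            ss.cone_spacing(coll)


class TestNearestSDistance:
    def test_exact_cases(self):
        m = ConeMosaic(
            positions=np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [3, 4]]),
            classes=np.array(["L", "M", "L", "S"]),
            patch_extent=(10, 10),
        )
        # 3-4-5 triangle with spacing passed explicitly as 1
        assert ss.nearest_s_distance(m, (0, 0), spacing=1.0) == pytest.approx(5.0)
        assert ss.nearest_s_distance(m, (3, 4), spacing=1.0) == pytest.approx(0.0)

    def test_matches_brute_force(self, jittered_mosaic):
        spacing = ss.cone_spacing(jittered_mosaic)
        s_pts = jittered_mosaic.positions_of("S")
        rng = np.random.default_rng(0)
        for point in rng.uniform(-8, 8, size=(10, 2)):
            expect = np.min(np.hypot(*(s_pts - point).T)) / spacing
            assert ss.nearest_s_distance(jittered_mosaic, point, spacing=spacing) == pytest.approx(expect)

    def test_invariant_to_LM_relabel(self, jittered_mosaic):
        swapped = ConeMosaic(
            positions=jittered_mosaic.positions.copy(),
            classes=np.where(
                jittered_mosaic.classes == "L",
                "M",
                np.where(jittered_mosaic.classes == "M", "L", jittered_mosaic.classes),
            ),
            patch_extent=jittered_mosaic.patch_extent,
        )
        assert ss.nearest_s_distance(swapped, (1.3, -2.0), spacing=1.0) == pytest.approx(
            ss.nearest_s_distance(jittered_mosaic, (1.3, -2.0), spacing=1.0)
        )

    def test_no_s_cones(self):
        m = ss.generate_mosaic(20, fraction_S=0.0, seed=1)
        with pytest.raises(MissingClassError):
            ss.nearest_s_distance(m, (0, 0), spacing=1.0)


def test_mosaic_table_round_trip(tmp_path, jittered_mosaic):
    path = tmp_path / "mosaic.tsv"
    write_mosaic(jittered_mosaic, path)
    back = read_mosaic(path)
    np.testing.assert_array_equal(back.positions, jittered_mosaic.positions)
    np.testing.assert_array_equal(back.classes, jittered_mosaic.classes)
    assert back.patch_extent == tuple(jittered_mosaic.patch_extent)
    assert back.nominal_spacing == jittered_mosaic.nominal_spacing
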