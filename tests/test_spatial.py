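"""Moran/LISA statistics against brute-force oracles, permutation inference
calibration, and quantile classing."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from hhci.spatial import (
    SpatialWeights,
    local_moran,
    morans_i,
    permutation_test,
    quantile_classes,
    queen_weights,
)

from conftest import brute_local_moran, brute_morans_i, nw_from_weights


def lattice_polys(rows, cols):
    return [
        Polygon([(c, r), (c + 1, r), (c + 1, r + 1), (c, r + 1)])
        for r in range(rows)
        for c in range(cols)
    ]


class TestWeights:
    def test_queen_center_of_3x3_has_eight_neighbors(self):
        w = queen_weights(lattice_polys(3, 3))
        center = 4
        assert len(w.neighbors[center]) == 8
        np.testing.assert_allclose(w.weights[center], 1 / 8)

    def test_two_cell_lattice_fully_weighted(self):
        w = queen_weights(lattice_polys(1, 2))
        assert w.neighbors[0].tolist() == [1]
        assert w.weights[0][0] == 1.0
        assert w.weights[1][0] == 1.0

    def test_single_polygon_warns_isolated(self):
        with pytest.warns(UserWarning, match="isolated"):
            w = queen_weights(lattice_polys(1, 1))
        assert w.s0 == 0

    def test_rook_excludes_corner_touches(self):
        w_queen = queen_weights(lattice_polys(2, 2))
        w_rook = queen_weights(lattice_polys(2, 2), criterion="rook")
        assert len(w_queen.neighbors[0]) == 3  # includes the diagonal
        assert len(w_rook.neighbors[0]) == 2

    def test_gal_round_trip(self):
        w = queen_weights(lattice_polys(3, 3))
        w2 = SpatialWeights.from_gal(w.to_gal())
        for a, b in zip(w.neighbors, w2.neighbors):
            np.testing.assert_array_equal(a, b)

    def test_row_standardization_sums_to_one(self):
        w = queen_weights(lattice_polys(4, 5))
        for wt in w.weights:
            assert wt.sum() == pytest.approx(1.0)


class TestMoransI:
    def test_checkerboard_on_rook_lattice_gives_minus_one(self):
        # every neighbor of a cell holds the opposite value, so z'Wz = -z'z
        polys = lattice_polys(4, 4)
        w = queen_weights(polys, criterion="rook")
        x = np.array([(r + c) % 2 for r in range(4) for c in range(4)], dtype=float)
        assert morans_i(x, w) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        w = queen_weights(lattice_polys(2, 3))
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(6), w)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        w = queen_weights(lattice_polys(5, 5))
        nw = nw_from_weights(w)
        for _ in range(5):
            x = rng.normal(size=25)
            assert morans_i(x, w) == pytest.approx(brute_morans_i(x, nw), abs=1e-12)

    def test_null_calibration_of_permutation_p(self):
        """On iid data the one-sided pseudo p is near-uniform: rejections at
        alpha=0.05 over 200 replicates stay within binomial bounds."""
        rng = np.random.default_rng(12)
        w = queen_weights(lattice_polys(5, 5))
        rejections = 0
        for rep in range(200):
            x = rng.normal(size=25)
            _, p, _ = permutation_test(x, w, permutations=999, seed=rep)
            rejections += p <= 0.05
        # Binomial(200, 0.05): central 99.9% range is about [1, 21]
        assert 1 <= rejections <= 21


class TestPermutationTest:
    def test_floor_pseudo_p_when_observed_exceeds_all(self):
        # a strong gradient on a path lattice beats every relabelling
        w = queen_weights(lattice_polys(1, 30))
        x = np.arange(30, dtype=float)
        _, p, perms = permutation_test(x, w, permutations=999, seed=0)
        assert p == pytest.approx(0.001)
        assert (perms < morans_i(x, w)).all()

    def test_single_permutation_worst_case_p_is_one(self):
        w = queen_weights(lattice_polys(1, 30))
        x = np.arange(30, dtype=float)
        # alternative='less': the observed strongly positive I is never
        # as-or-more extreme than a permuted value in the 'less' direction
        _, p, _ = permutation_test(x, w, permutations=1, seed=0, alternative="less")
        assert p == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        w = queen_weights(lattice_polys(4, 4))
        x = rng.normal(size=16)
        a = permutation_test(x, w, permutations=99, seed=5)
        b = permutation_test(x, w, permutations=99, seed=5)
        assert a[1] == b[1]
        np.testing.assert_array_equal(a[2], b[2])

    def test_p_invariant_under_unit_relabelling(self):
        """Exchangeability: permuting unit labels (and the weights with them)
        leaves the observed I unchanged."""
        rng = np.random.default_rng(8)
        w = queen_weights(lattice_polys(4, 4))
        x = rng.normal(size=16)
        perm = rng.permutation(16)
        inv = np.argsort(perm)
        pairs = [(int(inv[i]), int(inv[j])) for i in range(16)
                 for j in w.neighbors[i] if i < j]
        w2 = SpatialWeights.from_pairs(16, pairs)
        assert morans_i(x[perm], w2) == pytest.approx(morans_i(x, w), abs=1e-12)


class TestLocalMoran:
    def _block_fixture(self):
        """7x7 map: a high-valued 3x3 block in the middle of a low plain."""
        rng = np.random.default_rng(2)
        rows = cols = 7
        x = rng.normal(0.0, 0.5, size=rows * cols)
        for r in range(2, 5):
            for c in range(2, 5):
                x[r * cols + c] += 10.0
        return lattice_polys(rows, cols), x

    def test_block_interior_labelled_high_high(self):
        polys, x = self._block_fixture()
        w = queen_weights(polys)
        res = local_moran(x, w, permutations=999, alpha=0.05, seed=0)
        center = 3 * 7 + 3
        assert res.labels[center] == "HH"

    def test_zero_alpha_gates_every_label(self):
        polys, x = self._block_fixture()
        w = queen_weights(polys)
        res = local_moran(x, w, permutations=99, alpha=0.0, seed=0)
        assert set(res.labels) == {"NS"}

    def test_mean_local_equals_global(self):
        rng = np.random.default_rng(4)
        w = queen_weights(lattice_polys(6, 6))
        x = rng.normal(size=36)
        res = local_moran(x, w, permutations=9, seed=0)
        assert res.local_i.mean() == pytest.approx(morans_i(x, w), abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(6)
        w = queen_weights(lattice_polys(5, 5))
        nw = nw_from_weights(w)
        x = rng.normal(size=25)
        res = local_moran(x, w, permutations=9, seed=0)
        np.testing.assert_allclose(res.local_i, brute_local_moran(x, nw), atol=1e-12)

    def test_labels_match_quadrants(self):
        polys, x = self._block_fixture()
        w = queen_weights(polys)
        res = local_moran(x, w, permutations=199, alpha=0.05, seed=1)
        z = (x - x.mean()) / x.std()
        lag = w.lag(z)
        for i, lab in enumerate(res.labels):
            if lab == "HH":
                assert z[i] > 0 and lag[i] > 0
            elif lab == "LL":
                assert z[i] < 0 and lag[i] < 0
            elif lab == "HL":
                assert z[i] > 0 and lag[i] < 0
            elif lab == "LH":
                assert z[i] < 0 and lag[i] > 0
            else:
                assert res.pseudo_p[i] > 0.05 or lag[i] == 0


class TestQuantileClasses:
    def test_even_split_of_1_to_100(self):
        classes = quantile_classes(np.arange(1, 101), k=4)
        counts = np.bincount(classes)
        np.testing.assert_array_equal(counts, [25, 25, 25, 25])
        assert classes[0] == 0 and classes[-1] == 3

    def test_all_equal_collapses_to_single_class(self):
        with pytest.warns(UserWarning, match="distinct"):
            classes = quantile_classes(np.ones(10), k=5)
        assert set(classes) == {0}

    def test_balanced_sizes_on_random_399(self):
        rng = np.random.default_rng(9)
        classes = quantile_classes(rng.normal(size=399), k=5)
        counts = np.bincount(classes)
        assert counts.max() - counts.min() <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            quantile_classes(np.arange(5), k=1)
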