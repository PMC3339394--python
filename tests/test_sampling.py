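import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glompca import (
    MovieMatrix,
    PixelGrid,
    adaptive_sample,
    center_movie,
    covariation_energy,
    covariation_probabilities,
    local_covariation_norms,
    norm_probabilities,
    sample_with_replacement,
    sample_without_replacement,
    uniform_probabilities,
)
from conftest import explicit_local_matrix


def _movie(data, dims, centered=True):
    return MovieMatrix(np.asarray(data, float), PixelGrid(dims), centered=centered)


class TestNormProbabilities:
    def test_two_pixel_example(self):
        m = _movie([[3, 4], [0, 0]], (2, 1))
        p = norm_probabilities(m)
        np.testing.assert_allclose(p.p, [0.36, 0.64])

    def test_identical_columns_give_uniform(self):
        m = _movie(np.outer([1.0, -2.0, 0.5], np.ones(6)), (3, 2))
        np.testing.assert_allclose(norm_probabilities(m).p, 1 / 6)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        m = _movie(rng.standard_normal((20, 50)), (10, 5))
        p = norm_probabilities(m)
        oracle = np.array(
            [sum(x * x for x in m.data[:, j]) for j in range(50)]
        )
        oracle /= sum(sum(x * x for x in row) for row in m.data)
        np.testing.assert_allclose(p.p, oracle, atol=1e-12)

    def test_all_zero_movie_rejected(self):
        with pytest.raises(ValueError):
            norm_probabilities(_movie(np.zeros((3, 4)), (2, 2)))


class TestLocalCovariationNorms:
    @pytest.mark.parametrize("dims", [(4, 4), (8, 8), (7, 3), (3, 3, 3)])
    def test_matches_explicit_L_oracle(self, dims):
        rng = np.random.default_rng(sum(dims))
        m = center_movie(
            MovieMatrix(rng.standard_normal((10, int(np.prod(dims)))), PixelGrid(dims))
        )
        norms, total = local_covariation_norms(m)
        L = explicit_local_matrix(m)
        np.testing.assert_allclose(norms, np.linalg.norm(L, axis=0), atol=1e-10)
        assert total == pytest.approx(np.linalg.norm(L), abs=1e-10)

    def test_isolated_pixel_has_zero_norm(self):
        data = np.zeros((4, 9))
        data[:, 4] = [1, -1, 2, -2]  # centre of 3x3; all neighbours zero
        m = _movie(data, (3, 3))
        norms, _ = local_covariation_norms(m)
        assert norms[4] == 0.0

    def test_identical_timeseries_neighbour_counts(self):
        t = np.array([1.0, -0.5, 2.0, 0.25])
        m = _movie(np.outer(t, np.ones(9)), (3, 3))
        norms, _ = local_covariation_norms(m)
        tt = t @ t
        assert norms[4] == pytest.approx(np.sqrt(8) * tt)
        assert norms[0] == pytest.approx(np.sqrt(3) * tt)


class TestCovariationProbabilities:
    def test_matches_explicit_L_oracle(self):
        rng = np.random.default_rng(3)
        m = center_movie(MovieMatrix(rng.standard_normal((10, 16)), PixelGrid((4, 4))))
        p = covariation_probabilities(m)
        L = explicit_local_matrix(m)
        col_sq = np.linalg.norm(L, axis=0) ** 2
        np.testing.assert_allclose(p.p, col_sq / col_sq.sum(), atol=1e-10)

    def test_mass_confined_to_active_blob(self):
        data = np.zeros((5, 64))
        rng = np.random.default_rng(4)
        grid = PixelGrid((8, 8))
        blob = [grid.index(x, y) for x in (3, 4, 5) for y in (3, 4, 5)]
        data[:, blob] = rng.standard_normal((5, len(blob)))
        p = covariation_probabilities(_movie(data, (8, 8)))
        assert p.p[blob].sum() == pytest.approx(1.0)

    def test_identical_timeseries_interior_exceeds_edges(self):
        t = np.array([1.0, -2.0, 0.5])
        m = _movie(np.outer(t, np.ones(25)), (5, 5))
        p = covariation_probabilities(m)
        interior = [PixelGrid((5, 5)).index(x, y) for x in (1, 2, 3) for y in (1, 2, 3)]
        assert len(set(np.round(p.p[interior], 15))) == 1
        assert p.p[12] > p.p[0]

    def test_zero_local_covariation_raises(self):
        # 2x2-periodic tiling of orthogonal basis vectors: every Moore
        # neighbour pair is orthogonal, so L vanishes identically
        basis = np.eye(4)
        grid = PixelGrid((4, 4))
        data = np.zeros((4, 16))
        for j in range(16):
            x, y = grid.coords(j)
            data[:, j] = basis[(x % 2) + 2 * (y % 2)]
        with pytest.raises(ValueError):
            covariation_probabilities(_movie(data, (4, 4)))


class TestSampleWithReplacement:
    def test_degenerate_probability_duplicates_one_column(self):
        m = _movie([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]], (2, 1))
        p = norm_probabilities(m)  # all mass on pixel 0
        s = sample_with_replacement(m, 5, p, seed=0)
        assert np.all(s.indices == 0)
        np.testing.assert_allclose(
            s.C, np.outer([1, 2, 3], np.ones(5)) / np.sqrt(5.0)
        )

    def test_deterministic_given_seed(self, small_movie):
        movie, _ = small_movie
        p = norm_probabilities(movie)
        a = sample_with_replacement(movie, 20, p, seed=9)
        b = sample_with_replacement(movie, 20, p, seed=9)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.C, b.C)

    def test_empirical_frequencies_match_probabilities(self):
        from glompca import SamplingProbabilities

        m = _movie(np.ones((3, 4)), (2, 2))
        p_target = np.array([0.1, 0.2, 0.3, 0.4])
        probs = SamplingProbabilities(p_target, "uniform")
        c = 10_000
        s = sample_with_replacement(m, c, probs, seed=123)
        freq = np.bincount(s.indices, minlength=4) / c
        se = np.sqrt(p_target * (1 - p_target) / c)
        assert np.all(np.abs(freq - p_target) <= 3 * se)

    def test_rescaling_applied(self, small_movie):
        movie, _ = small_movie
        p = norm_probabilities(movie)
        s = sample_with_replacement(movie, 10, p, seed=1)
        j = s.indices[0]
        expected = movie.data[:, j] / np.sqrt(10 * p.p[j])
        np.testing.assert_allclose(s.C[:, 0], expected)


class TestSampleWithoutReplacement:
    def test_exhaustive_draw_is_column_permutation(self, random_movie):
        p = norm_probabilities(random_movie)
        s = sample_without_replacement(random_movie, random_movie.n, p, seed=2)
        assert sorted(s.indices) == list(range(random_movie.n))
        np.testing.assert_allclose(s.C, random_movie.data[:, s.indices])

    def test_indices_distinct(self, small_movie):
        movie, _ = small_movie
        p = covariation_probabilities(movie)
        s = sample_without_replacement(movie, 50, p, seed=3)
        assert len(np.unique(s.indices)) == s.c == 50

    def test_single_draw_frequency_matches_p(self):
        from glompca import SamplingProbabilities

        m = _movie(np.ones((3, 4)), (2, 2))
        p_target = np.array([0.1, 0.2, 0.3, 0.4])
        probs = SamplingProbabilities(p_target, "uniform")
        n_runs = 8000
        first = np.array(
            [sample_without_replacement(m, 1, probs, seed=s).indices[0]
             for s in range(n_runs)]
        )
        freq = np.bincount(first, minlength=4) / n_runs
        se = np.sqrt(p_target * (1 - p_target) / n_runs)
        assert np.all(np.abs(freq - p_target) <= 3 * se)

    def test_c_exceeding_support_raises(self):
        from glompca import SamplingProbabilities

        m = _movie(np.ones((3, 4)), (2, 2))
        probs = SamplingProbabilities(np.array([0.5, 0.5, 0.0, 0.0]), "uniform")
        with pytest.raises(ValueError):
            sample_without_replacement(m, 3, probs, seed=0)


class TestCovariationEnergy:
    def test_full_empty_and_duplicate_index_sets(self):
        norms = np.array([3.0, 4.0, 0.0, 1.0])
        total = np.linalg.norm(norms)
        assert covariation_energy(range(4), norms, total) == pytest.approx(1.0)
        assert covariation_energy([], norms, total) == 0.0
        dup = covariation_energy([1, 1, 1, 0], norms, total)
        dedup = covariation_energy([0, 1], norms, total)
        assert dup == pytest.approx(dedup)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            covariation_energy([0], np.zeros(3), 0.0)


class TestAdaptiveSample:
    def test_energy_saturates_on_concentrated_movie(self):
        data = np.zeros((5, 64))
        rng = np.random.default_rng(5)
        grid = PixelGrid((8, 8))
        blob = [grid.index(x, y) for x in (3, 4, 5) for y in (3, 4, 5)]
        data[:, blob] = rng.standard_normal((5, len(blob)))
        m = _movie(data, (8, 8))
        s = adaptive_sample(m, threshold=1.0, seed=0)
        assert set(s.indices) <= set(blob)

    def test_tiny_threshold_gives_single_pixel(self, small_movie):
        movie, _ = small_movie
        s = adaptive_sample(movie, threshold=1e-12, seed=0)
        assert s.c == 1

    def test_threshold_is_tight(self, small_movie):
        movie, _ = small_movie
        norms, total = local_covariation_norms(movie)
        s = adaptive_sample(movie, threshold=0.95, seed=7)
        full = covariation_energy(s.indices, norms, total)
        trimmed = covariation_energy(s.indices[:-1], norms, total)
        assert full >= 0.95
        assert trimmed < 0.95


class TestProbabilityInvariants:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        m = center_movie(MovieMatrix(rng.standard_normal((6, 20)), PixelGrid((5, 4))))
        for maker in (uniform_probabilities, norm_probabilities, covariation_probabilities):
            p = maker(m)
            assert np.all(p.p >= 0)
            assert p.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_strategy_energy_ordering_on_localised_sources(self, small_movie):
        movie, _ = small_movie
        norms, total = local_covariation_norms(movie)
        pu = uniform_probabilities(movie)
        pn = norm_probabilities(movie)
        pc = covariation_probabilities(movie)
        c = round(0.05 * movie.n)
        e = {"uniform": [], "norm": [], "covariation": []}
        for seed in range(20):
            su = sample_with_replacement(movie, c, pu, seed)
            sn = sample_with_replacement(movie, c, pn, seed)
            sc = sample_without_replacement(movie, c, pc, seed)
            for key, s in (("uniform", su), ("norm", sn), ("covariation", sc)):
                e[key].append(covariation_energy(s.indices, norms, total))
        assert np.mean(e["covariation"]) > np.mean(e["norm"]) > np.mean(e["uniform"])
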