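import itertools
from fractions import Fraction
from math import comb, log

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import beta as beta_dist

from pipedesign.contours import (
    Contour,
    TrialData,
    above_mtc_probability,
    contour_log_probability,
    contour_posterior,
    enumerate_contours,
    estimate_surface,
    modal_contour,
    tail_probability,
    update_posterior,
)
from pipedesign.priors import BetaGrid, PriorSpec, calibrate_grid


def brute_force_upsets(I, J):
    """Oracle: filter all 2^(I*J) binary matrices for the up-set property."""
    out = []
    for bits in itertools.product([0, 1], repeat=I * J):
        m = np.array(bits).reshape(I, J)
        ok = True
        for i in range(I):
            for j in range(J):
                if m[i, j] == 1:
                    if i + 1 < I and m[i + 1, j] == 0:
                        ok = False
                    if j + 1 < J and m[i, j + 1] == 0:
                        ok = False
        if ok:
            out.append(m)
    return out


class TestTrialData:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrialData(n=np.zeros((2, 2), int), x=np.ones((2, 2), int), history=[])

    def test_add_cohort_tracks_history(self):
        data = TrialData.empty((2, 2))
        data.add_cohort((0, 0), 2, 1)
        data.add_cohort((1, 1), 2, 0)
        assert data.n.sum() == 4
        assert data.x[0, 0] == 1
        assert data.history == [(1, (0, 0), 2, 1), (2, (1, 1), 2, 0)]
        assert data.doses_given() == {(0, 0), (1, 1)}


class TestContour:
    def test_matrix_round_trip(self):
        above = np.array([[0, 1], [1, 1]])
        c = Contour.from_matrix(above)
        assert np.array_equal(c.above, above)
        assert c.heights.tolist() == [1, 0]

    def test_rejects_non_upset(self):
        with pytest.raises(ValueError):
            Contour.from_matrix(np.array([[1, 0], [0, 0]]))
        with pytest.raises(ValueError):
            Contour(heights=[0, 2], n_cols=2)  # increasing heights


class TestUpdatePosterior:
    def test_published_update(self):
        prior = BetaGrid(a=np.array([[0.39]]), b=np.array([[0.61]]))
        data = TrialData(n=np.array([[10]]), x=np.array([[1]]), history=[])
        post = update_posterior(prior, data)
        assert post.a[0, 0] == pytest.approx(1.39)
        assert post.b[0, 0] == pytest.approx(9.61)

    def test_no_data_is_identity(self, weak_prior_study1):
        data = TrialData.empty((6, 6))
        post = update_posterior(weak_prior_study1, data)
        assert np.array_equal(post.a, weak_prior_study1.a)
        assert np.array_equal(post.b, weak_prior_study1.b)

    def test_all_events(self):
        prior = BetaGrid(a=np.array([[1.0]]), b=np.array([[1.0]]))
        data = TrialData(n=np.array([[3]]), x=np.array([[3]]), history=[])
        post = update_posterior(prior, data)
        assert (post.a[0, 0], post.b[0, 0]) == (4.0, 1.0)

    def test_shape_mismatch(self):
        prior = BetaGrid(a=np.ones((2, 2)), b=np.ones((2, 2)))
        with pytest.raises(ValueError):
            update_posterior(prior, TrialData.empty((3, 3)))


class TestTailProbability:
    def test_uniform(self):
        g = BetaGrid(a=np.array([[1.0]]), b=np.array([[1.0]]))
        assert tail_probability(g, 0.5)[0, 0] == pytest.approx(0.5)

    def test_calibrated_median(self):
        g = BetaGrid(a=np.array([[0.38858]]), b=np.array([[0.61142]]))
        assert tail_probability(g, 0.3)[0, 0] == pytest.approx(0.5, abs=1e-4)

    def test_limit_near_one(self):
        g = BetaGrid(a=np.array([[2.0]]), b=np.array([[5.0]]))
        assert tail_probability(g, 0.999999)[0, 0] == pytest.approx(1.0, abs=1e-4)

    def test_theta_range(self):
        g = BetaGrid(a=np.ones((1, 1)), b=np.ones((1, 1)))
        with pytest.raises(ValueError):
            tail_probability(g, 1.0)


class TestEnumerateContours:
    def test_two_by_two_has_six(self):
        assert len(enumerate_contours(2, 2)) == 6

    def test_one_by_one(self):
        cs = enumerate_contours(1, 1)
        assert len(cs) == 2
        mats = {tuple(c.above.ravel()) for c in cs}
        assert mats == {(0,), (1,)}

    def test_three_by_two_matches_brute_force(self):
        assert len(enumerate_contours(3, 2)) == len(brute_force_upsets(3, 2)) == 10

    @pytest.mark.parametrize("I,J", [(i, j) for i in range(1, 5) for j in range(1, 5)])
    def test_count_law(self, I, J):
        cs = enumerate_contours(I, J)
        assert len(cs) == comb(I + J, I)
        oracle = {tuple(m.ravel()) for m in brute_force_upsets(I, J)}
        assert {tuple(c.above.ravel()) for c in cs} == oracle

    def test_no_duplicates(self):
        cs = enumerate_contours(4, 3)
        assert len({tuple(c.heights) for c in cs}) == len(cs)

    def test_cap(self):
        with pytest.raises(ValueError, match="184756"):
            enumerate_contours(10, 10, cap=10**5)


class TestContourLogProbability:
    def test_uniform_half(self):
        p = np.full((2, 2), 0.5)
        for c in enumerate_contours(2, 2):
            assert contour_log_probability(p, c) == pytest.approx(log(0.0625))

    def test_certain_below(self):
        p = np.ones((2, 2))
        all_below = Contour(heights=[2, 2], n_cols=2)
        assert contour_log_probability(p, all_below) == pytest.approx(0.0)

    def test_derived_product(self):
        p = np.array([[0.9, 0.6], [0.6, 0.1]])
        top_only = Contour.from_matrix(np.array([[0, 0], [0, 1]]))
        assert contour_log_probability(p, top_only) == pytest.approx(log(0.9 * 0.6 * 0.6 * 0.9))

    def test_zero_factor_gives_neg_inf(self):
        p = np.array([[0.0]])
        below = Contour(heights=[1], n_cols=1)
        assert contour_log_probability(p, below) == -np.inf


class TestContourPosterior:
    def test_symmetry_six_equal(self):
        dist = contour_posterior(np.full((2, 2), 0.5))
        assert np.allclose(dist.probs, 1 / 6)

    def test_single_cell(self):
        dist = contour_posterior(np.array([[0.8]]))
        by_height = {tuple(c.heights): pr for c, pr in zip(dist.contours, dist.probs)}
        assert by_height[(1,)] == pytest.approx(0.8)
        assert by_height[(0,)] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=9, max_size=9).map(
            lambda v: np.array(v).reshape(3, 3)
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_normalization(self, p):
        dist = contour_posterior(p)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestCompletenessIdentity:
    @pytest.mark.parametrize("shape", [(1, 1), (2, 2), (3, 3), (2, 4), (1, 9)])
    def test_products_over_all_matrices_sum_to_one(self, shape):
        rng = np.random.default_rng(sum(shape))
        p = rng.uniform(0.05, 0.95, size=shape)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=p.size):
            m = np.array(bits).reshape(shape)
            total += np.prod(np.where(m == 1, 1 - p, p))
        assert total == pytest.approx(1.0, abs=1e-12)


class TestModalContour:
    def test_derived_argmax(self):
        p = np.array([[0.9, 0.6], [0.6, 0.1]])
        dist = contour_posterior(p)
        c = modal_contour(dist, np.random.default_rng(0))
        assert np.array_equal(c.above, [[0, 0], [0, 1]])
        # brute-force check over all six products
        best = max(contour_log_probability(p, k) for k in enumerate_contours(2, 2))
        assert contour_log_probability(p, c) == pytest.approx(best)
        assert np.exp(best) == pytest.approx(0.2916)

    def test_tie_broken_reproducibly(self):
        dist = contour_posterior(np.full((2, 2), 0.5))
        picks = {tuple(modal_contour(dist, np.random.default_rng(s)).heights) for s in range(40)}
        assert len(picks) > 1  # random among the six
        c1 = modal_contour(dist, np.random.default_rng(7))
        c2 = modal_contour(dist, np.random.default_rng(7))
        assert c1 == c2

    def test_single_cell(self):
        dist = contour_posterior(np.array([[0.8]]))
        assert modal_contour(dist, np.random.default_rng(0)).heights.tolist() == [1]


class TestAboveMtcProbability:
    def test_exact_two_by_two(self):
        # oracle in exact rationals over the six enumerated up-sets
        upsets = brute_force_upsets(2, 2)
        w = [Fraction(1, len(upsets))] * len(upsets)
        q_exact = np.zeros((2, 2), dtype=object)
        for m, wk in zip(upsets, w):
            q_exact = q_exact + wk * m
        dist = contour_posterior(np.full((2, 2), 0.5))
        q = above_mtc_probability(dist)
        expected = np.array([[Fraction(1, 6), Fraction(1, 2)], [Fraction(1, 2), Fraction(5, 6)]])
        assert np.array_equal(q_exact, expected)
        assert np.allclose(q, expected.astype(float), atol=1e-12)

    def test_single_cell(self):
        dist = contour_posterior(np.array([[0.8]]))
        assert above_mtc_probability(dist)[0, 0] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=6, max_size=6).map(
            lambda v: np.array(v).reshape(2, 3)
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_both_indices(self, p):
        q = above_mtc_probability(contour_posterior(p))
        assert np.all(np.diff(q, axis=0) >= -1e-12)
        assert np.all(np.diff(q, axis=1) >= -1e-12)


class TestRigidity:
    """Contour movement after one cohort at a closest-below dose."""

    @pytest.fixture
    def setup(self):
        med = np.array([[0.05, 0.10, 0.20], [0.10, 0.20, 0.35], [0.20, 0.35, 0.50]])
        prior = calibrate_grid(PriorSpec(medians=med, strength=1 / 9, theta=0.3))
        dist0 = contour_posterior(tail_probability(prior, 0.3))
        c0 = modal_contour(dist0, np.random.default_rng(0))
        return prior, c0

    def test_prior_modal_is_unique_and_expected(self, setup):
        prior, c0 = setup
        assert c0.heights.tolist() == [3, 2, 1]  # above iff median > 0.3

    def test_one_dlt_flips_dose_above(self, setup):
        prior, c0 = setup
        dose = (1, 1)  # a closest-below dose of c0
        data = TrialData.empty((3, 3))
        data.add_cohort(dose, 2, 1)
        post = update_posterior(prior, data)
        p = tail_probability(post, 0.3)
        assert p[dose] < 0.5  # posterior mass tips above theta
        c2 = Contour(heights=[3, 1, 1], n_cols=3)  # c0 with (1,1) reclassified
        assert contour_log_probability(p, c2) > contour_log_probability(p, c0)
        new_modal = modal_contour(contour_posterior(p), np.random.default_rng(0))
        assert new_modal.is_above(dose)

    def test_zero_dlts_leave_modal_unchanged(self, setup):
        prior, c0 = setup
        data = TrialData.empty((3, 3))
        data.add_cohort((1, 1), 2, 0)
        p = tail_probability(update_posterior(prior, data), 0.3)
        assert modal_contour(contour_posterior(p), np.random.default_rng(0)) == c0

    def test_density_comparison(self):
        assert beta_dist.pdf(0.3, 1.39, 9.61) > beta_dist.pdf(0.3, 0.39, 0.61)


class TestEstimateSurface:
    def test_single_theta_matches_modal(self, weak_prior_study1):
        rng = np.random.default_rng(3)
        dist = contour_posterior(tail_probability(weak_prior_study1, 0.3))
        expected = modal_contour(dist, np.random.default_rng(3))
        [(t, c)] = estimate_surface(weak_prior_study1, [0.3], np.random.default_rng(3))
        assert t == 0.3 and c == expected

    def test_extreme_thetas(self, weak_prior_study1):
        surface = estimate_surface(weak_prior_study1, [0.0001, 0.9999])
        assert np.all(surface[0][1].above == 1)  # everything above a tiny target
        assert np.all(surface[1][1].above == 0)

    def test_nested_above_sets(self, weak_prior_study1):
        thetas = [0.1, 0.2, 0.3, 0.5, 0.7, 0.9]
        surface = estimate_surface(weak_prior_study1, thetas, np.random.default_rng(0))
        for (_, lo), (_, hi) in zip(surface, surface[1:]):
            # above-set shrinks as theta grows <=> heights nondecreasing
            assert np.all(lo.heights <= hi.heights)

    def test_peaked_posterior_recovers_bands(self):
        # near-degenerate betas at 0.1 and 0.6: the 0.3-contour must split them
        a = np.array([[100.0, 600.0], [600.0, 600.0]])
        b = np.array([[900.0, 400.0], [400.0, 400.0]])
        post = BetaGrid(a=a, b=b)
        [(_, c)] = estimate_surface(post, [0.3])
        assert np.array_equal(c.above, [[0, 1], [1, 1]])

    def test_rejects_unsorted_thetas(self, weak_prior_study1):
        with pytest.raises(ValueError):
            estimate_surface(weak_prior_study1, [0.3, 0.2])
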