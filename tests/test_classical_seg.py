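"""Tests for the ant-colony, region-growing and clustering segmenters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medsegmesh import classical_seg as cs
from medsegmesh.errors import InvalidParameterError, OutOfRangeError
from medsegmesh.phantom_eval import aom, make_disk_phantom


class TestFeatureDistance:
    def test_identical_is_zero(self):
        f = cs.AntFeature(10, 2, 9)
        assert cs.feature_distance(f, f) == 0.0

    def test_three_four_five(self):
        assert cs.feature_distance((1, 2, 3), (4, 6, 3), (1, 1, 1)) == pytest.approx(5.0)

    @given(st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_weight_scaling_homogeneity(self, s):
        d1 = cs.feature_distance((1, 2, 3), (4, 0, 7), (1, 1, 1))
        d2 = cs.feature_distance((1, 2, 3), (4, 0, 7), (s, s, s))
        assert d2 == pytest.approx(np.sqrt(s) * d1)


class TestIndicatorAndGuidance:
    @pytest.mark.parametrize("dist,expected", [(0.0, 1), (2.0, 1), (2.0 + 1e-9, 0)])
    def test_radius_threshold(self, dist, expected):
        assert cs.neighborhood_indicator(dist, 2.0) == expected

    def test_guiding_value_ratios(self):
        center = cs.AntFeature(0, 0, 0)
        f_b = cs.AntFeature(2.0, 0, 0)  # distance b
        f_2b = cs.AntFeature(4.0, 0, 0)
        assert cs.guiding_value(f_b, center, 2.0) == pytest.approx(1.0)
        assert cs.guiding_value(f_2b, center, 2.0) == pytest.approx(0.5)

    def test_guiding_value_capped_near_zero(self):
        c = cs.AntFeature(1, 1, 1)
        v = cs.guiding_value(c, c, 2.0)
        assert np.isfinite(v) and v == pytest.approx(2.0 / 1e-9)


class TestTransitionProbabilities:
    def test_single_candidate(self):
        assert cs.cluster_transition_probability([2.0], [3.0], 1, 1) == pytest.approx([1.0])

    def test_uniform_inputs(self):
        p = cs.cluster_transition_probability([1, 1, 1, 1], [1, 1, 1, 1], 1, 2)
        assert p == pytest.approx([0.25] * 4)

    def test_direct_ratio(self):
        p = cs.cluster_transition_probability([1, 2], [1, 1], 1, 1)
        assert p == pytest.approx([1 / 3, 2 / 3])

    def test_all_zero_falls_back_to_uniform(self):
        p = cs.cluster_transition_probability([0, 0], [1, 1], 1, 1)
        assert p == pytest.approx([0.5, 0.5])

    @given(
        st.lists(st.floats(0, 10), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 10), min_size=6, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization_property(self, tau, eta):
        n = len(tau)
        p = cs.cluster_transition_probability(tau, eta[:n], 1.2, 0.7)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


class TestPheromoneDynamics:
    def test_update_substitution(self):
        assert cs.pheromone_update(1.0, 0.9, 0.5) == pytest.approx(1.4)

    def test_geometric_decay(self):
        tau = 1.0
        values = []
        for _ in range(30):
            tau = float(cs.pheromone_update(tau, 0.8, 0.0))
            values.append(tau)
        assert values[-1] < 1e-2 and all(np.diff(values) < 0)

    def test_persistence_at_rho_one(self):
        assert cs.pheromone_update(3.0, 1.0, 0.0) == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "sigma,beta,delta,expected",
        [(0.0, 3.0, 0.5, 1.0), (1.0, 2.0, 0.2, (1 + 1 / 1.2) ** 2)],
    )
    def test_weighting_function(self, sigma, beta, delta, expected):
        assert cs.pheromone_weight(sigma, beta, delta) == pytest.approx(expected)

    def test_weighting_saturates(self):
        w = cs.pheromone_weight(1e9, 2.0, 0.5)
        assert w == pytest.approx((1 + 1 / 0.5) ** 2, rel=1e-6)

    def test_deposit_amount(self):
        assert cs.deposit_amount(0.0, 0.1, 2.0) == pytest.approx(0.1)
        assert cs.deposit_amount(0.25, 0.1, 2.0) == pytest.approx(0.6)

    def test_field_stays_nonnegative(self, rng):
        field = cs.PheromoneField((8, 8))
        for _ in range(200):
            field.deposit((rng.integers(8), rng.integers(8)), float(rng.uniform(0, 1)))
            field.evaporate(0.7)
        assert (field.tau >= 0).all()


class TestMotionTransition:
    def test_uniform_everything_uniform_probs(self):
        p = cs.AcoParams()
        sigma = np.zeros((5, 5))
        cands, probs = cs.motion_transition((2, 2), (5, 5), sigma, p, prev_dir=None)
        assert len(cands) == 8
        assert probs == pytest.approx([1 / 8] * 8)

    def test_probabilities_sum_to_one(self, rng):
        p = cs.AcoParams()
        sigma = rng.uniform(0, 5, (6, 6))
        for pos in [(0, 0), (2, 3), (5, 5)]:
            _, probs = cs.motion_transition(pos, (6, 6), sigma, p, prev_dir=4)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_forward_inertia_dominates_on_uniform_field(self):
        p = cs.AcoParams()
        sigma = np.ones((5, 5))
        prev = 4  # moving +x
        cands, probs = cs.motion_transition((2, 2), (5, 5), sigma, p, prev_dir=prev)
        assert cands[int(np.argmax(probs))] == prev


class TestWindowSimilarity:
    def test_identical_windows_zero(self):
        w = np.arange(9.0).reshape(3, 3)
        raw = cs.window_raw_terms(w, w)
        assert cs.window_similarity(raw, (1.0, 1.0, 1.0), (0.4, 0.3, 0.3)) == 0.0

    def test_pair_attaining_all_maxima(self):
        w1 = np.zeros((3, 3))
        w2 = np.full((3, 3), 10.0)
        raw = cs.window_raw_terms(w1, w2, value_range=(0, 10))
        dh = cs.window_similarity(raw, raw, (0.4, 0.3, 0.3))
        # std term is 0/0 -> 0, so the total is a + c, not 1
        assert dh == pytest.approx(0.4 + 0.3)

    def test_constant_window_pair_hand_computation(self):
        a, b, c = 0.5, 0.2, 0.3
        w1 = np.zeros((3, 3))
        w2 = np.full((3, 3), 10.0)
        raw = cs.window_raw_terms(w1, w2, value_range=(0, 10))
        maxima = raw  # the only pair evaluated
        assert cs.window_similarity(raw, maxima, (a, b, c)) == pytest.approx(a + c)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        w1, w2 = r.uniform(0, 255, (3, 3)), r.uniform(0, 255, (3, 3))
        raw = cs.window_raw_terms(w1, w2)
        dh = cs.window_similarity(raw, raw, (0.4, 0.3, 0.3))
        assert 0.0 <= dh <= 1.0 + 1e-12

    def test_shape_mismatch_rejected(self):
        from medsegmesh.errors import ShapeMismatchError

        with pytest.raises(ShapeMismatchError):
            cs.window_raw_terms(np.zeros((3, 3)), np.zeros((5, 5)))


@pytest.fixture(scope="module")
def small_params():
    return cs.AcoParams(seed=42, n_ants=20, n_iter=10, walk_steps=50)


class TestAcoSegment:
    def test_separable_regions_exact(self, small_params):
        img, truth = make_disk_phantom(shape=(64, 64), radius=18, fg=200, bg=0)
        lab = cs.aco_segment(img, 2, small_params)
        assert aom(truth == 1, lab == 1) == 1.0
        assert aom(truth == 0, lab == 0) == 1.0

    def test_noisy_regions_high_overlap(self, small_params):
        img, truth = make_disk_phantom(
            shape=(64, 64), radius=18, fg=200, bg=0, noise_percent=3, seed=1
        )
        lab = cs.aco_segment(img, 2, small_params)
        assert aom(truth == 1, lab == 1) >= 0.95
        assert aom(truth == 0, lab == 0) >= 0.95

    def test_fixed_seed_reproducible(self, small_params):
        img, _ = make_disk_phantom(shape=(32, 32), radius=9, fg=200, bg=0)
        p = cs.AcoParams(seed=7, n_ants=10, n_iter=5, walk_steps=30)
        assert np.array_equal(cs.aco_segment(img, 2, p), cs.aco_segment(img, 2, p))

    def test_too_many_clusters_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(InvalidParameterError):
            cs.aco_segment(img, 3, cs.AcoParams(seed=0, n_iter=1, n_ants=1, walk_steps=1))


class TestRegionGrow:
    def test_constant_image_single_region(self):
        img = np.full((16, 16), 5.0)
        lab = cs.region_grow(img, [(8, 8)], tol=1.0)
        assert (lab == 1).all()

    def test_two_blobs_only_seeded_one_grows(self):
        img = np.zeros((20, 40))
        img[5:10, 5:10] = 200.0
        img[5:10, 25:30] = 200.0
        lab = cs.region_grow(img, [(7, 7)], tol=10.0)
        assert (lab[5:10, 5:10] == 1).all()
        assert (lab[5:10, 25:30] == 0).all()

    def test_zero_tolerance_exact_matches_only(self, rng):
        img = rng.normal(100, 20, (12, 12))
        lab = cs.region_grow(img, [(6, 6)], tol=0.0)
        assert lab[6, 6] == 1 and (lab == 1).sum() == 1

    def test_out_of_bounds_seed(self):
        with pytest.raises(OutOfRangeError):
            cs.region_grow(np.zeros((4, 4)), [(10, 0)], tol=1.0)


class TestBaselines:
    @pytest.mark.parametrize("method", ["kmeans", "fcm", "kfcm"])
    def test_two_constant_regions_recovered(self, method):
        img, truth = make_disk_phantom(shape=(48, 48), radius=14, fg=200, bg=0)
        lab = cs.baseline_segment(img, method, 2, seed=0)
        assert aom(truth == 1, lab == 1) == 1.0

    @pytest.mark.parametrize("method", ["kmeans", "fcm", "kfcm"])
    def test_deterministic_given_seed(self, method):
        img, _ = make_disk_phantom(shape=(32, 32), radius=9, fg=150, bg=20, noise_percent=5, seed=3)
        a = cs.baseline_segment(img, method, 3, seed=11)
        b = cs.baseline_segment(img, method, 3, seed=11)
        assert np.array_equal(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.baseline_segment(np.zeros((4, 4)), "spectral", 2)

    def test_label_permutation_equivalence_across_seeds(self):
        img, truth = make_disk_phantom(shape=(32, 32), radius=10, fg=180, bg=10)
        a = cs.baseline_segment(img, "kmeans", 2, seed=0)
        b = cs.baseline_segment(img, "kmeans", 2, seed=99)
        assert np.array_equal(a, b)  # labels are center-ordered, so identical
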