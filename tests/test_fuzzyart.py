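"""Fuzzy ART clustering: unit rules, hand traces, and the independent
straight-line flow oracle."""

import numpy as np
import pytest

from appendix_us.errors import NoClustersError, NoPixelsError
from appendix_us.fascia import RoiMask
from appendix_us.fuzzyart import (
    NON_ROI,
    ClusterAssignment,
    FuzzyARTParams,
    cluster_pixels,
    cluster_roi,
    node_output,
    normalize_brightness,
    quantize,
    select_winner,
    update_weight,
    vigilance_test,
)
from appendix_us.imgio import BinaryImage, GrayscaleImage
from conftest import fuzzyart_trace


class TestUnitRules:
    def test_normalization_endpoints_and_midpoint(self):
        img = GrayscaleImage(np.array([[0, 255, 128]], dtype=np.uint8))
        np.testing.assert_allclose(
            normalize_brightness(img), [[0.0, 1.0, 128 / 255]]
        )

    @pytest.mark.parametrize(
        "w, x, expected", [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.8, 0.5, 0.3)]
    )
    def test_node_output_is_absolute_distance(self, w, x, expected):
        assert node_output(w, x, 1.0) == pytest.approx(expected)

    def test_select_winner_minimum_and_ties(self):
        assert select_winner([0.2, 0.05, 0.9]) == 1
        assert select_winner([0.3, 0.3]) == 0
        assert select_winner([0.7]) == 0
        with pytest.raises(NoClustersError):
            select_winner([])

    def test_vigilance_pass_fail_and_exact_match(self):
        p = FuzzyARTParams(rho=0.7)
        assert vigilance_test(0.8, 0.8, p)  # min = 0.8 > 0.7
        assert not vigilance_test(0.2, 0.9, FuzzyARTParams(rho=0.5))
        # exact-match dialect: identical pattern resonates at any vigilance
        assert vigilance_test(0.3, 0.3, FuzzyARTParams(rho=0.99))

    @pytest.mark.parametrize(
        "alpha, w, x, expected",
        [(1.0, 0.8, 0.4, 0.4), (0.0, 0.8, 0.4, 0.8), (0.5, 0.8, 0.4, 0.6)],
    )
    def test_update_weight_rule(self, alpha, w, x, expected):
        assert update_weight(w, x, alpha) == pytest.approx(expected)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            FuzzyARTParams(rho=0.0)
        with pytest.raises(ValueError):
            FuzzyARTParams(alpha=1.5)
        with pytest.raises(ValueError):
            FuzzyARTParams(max_clusters=0)


class TestClusterPixels:
    def test_hand_traced_three_pixel_example(self):
        params = FuzzyARTParams(rho=0.5, alpha=1.0)
        labels, state = cluster_pixels([0.9, 0.9, 0.1], params)
        assert labels.tolist() == [0, 0, 1]
        assert state.weights == pytest.approx([0.9, 0.1])
        assert state.counts == [2, 1]

    def test_identical_inputs_form_one_cluster(self):
        labels, state = cluster_pixels([0.4] * 20, FuzzyARTParams(rho=0.85))
        assert state.n_clusters == 1
        assert (labels == 0).all()
        assert state.weights[0] == pytest.approx(0.4)

    def test_maximum_vigilance_isolates_distinct_values(self):
        values = [0.1, 0.3, 0.5, 0.7]
        labels, state = cluster_pixels(values, FuzzyARTParams(rho=1.0, max_clusters=8))
        assert state.n_clusters == 4
        assert labels.tolist() == [0, 1, 2, 3]

    def test_cap_reached_assigns_nearest_without_update(self):
        params = FuzzyARTParams(rho=0.95, alpha=1.0, max_clusters=2)
        labels, state = cluster_pixels([0.1, 0.8, 0.75], params)
        assert state.n_clusters == 2
        assert labels.tolist() == [0, 1, 1]
        assert state.weights == pytest.approx([0.1, 0.8])  # no update past the cap

    def test_deterministic_repeat_runs(self):
        rng = np.random.default_rng(2)
        values = rng.random(500)
        params = FuzzyARTParams(rho=0.6, alpha=0.3, max_clusters=8)
        l1, s1 = cluster_pixels(values, params)
        l2, s2 = cluster_pixels(values, params)
        np.testing.assert_array_equal(l1, l2)
        assert s1.weights == s2.weights and s1.counts == s2.counts

    def test_empty_input_raises(self):
        with pytest.raises(NoPixelsError):
            cluster_pixels([], FuzzyARTParams())

    def test_cluster_count_bounded_by_distinct_values_and_cap(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            values = rng.choice([0.0, 0.2, 0.5, 0.9], size=30)
            params = FuzzyARTParams(
                rho=float(rng.uniform(0.1, 1.0)),
                alpha=float(rng.uniform(0, 1)),
                max_clusters=int(rng.integers(1, 6)),
            )
            _, state = cluster_pixels(values, params)
            bound = min(np.unique(values).size, params.max_clusters)
            assert 1 <= state.n_clusters <= bound

    def test_two_separated_modes_yield_two_clusters(self):
        rng = np.random.default_rng(21)
        lo = rng.uniform(0.02, 0.08, 40)
        hi = rng.uniform(0.90, 0.96, 40)
        values = np.concatenate([lo, hi])
        rng.shuffle(values)
        _, state = cluster_pixels(values, FuzzyARTParams(rho=0.5, alpha=0.5))
        assert state.n_clusters >= 2

    def test_fast_learning_weights_never_increase(self):
        # alpha = 1: w' = min(x, w) <= w, so each weight trajectory is
        # non-increasing; verified by re-running on every prefix
        rng = np.random.default_rng(33)
        for _ in range(20):
            values = rng.random(int(rng.integers(2, 30)))
            params = FuzzyARTParams(
                rho=float(rng.uniform(0.1, 0.95)), alpha=1.0, max_clusters=6
            )
            prev: dict[int, float] = {}
            for n in range(1, values.size + 1):
                _, state = cluster_pixels(values[:n], params)
                for j, w in enumerate(state.weights):
                    assert w <= prev.get(j, 1.0) + 1e-12
                    prev[j] = w

    def test_matches_straight_line_flow_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            n = int(rng.integers(1, 13))
            values = np.round(rng.random(n), 3)
            if rng.random() < 0.3:  # force duplicates sometimes
                values = rng.choice(values, size=n)
            rho = float(rng.uniform(0.05, 1.0))
            alpha = float(rng.uniform(0.0, 1.0))
            cap = int(rng.integers(1, 8))
            params = FuzzyARTParams(rho=rho, alpha=alpha, max_clusters=cap)
            labels, state = cluster_pixels(values, params)
            olabels, oweights, _ = fuzzyart_trace(values, rho, alpha, 1.0, cap)
            assert labels.tolist() == olabels
            assert state.weights == oweights  # bit-identical floats


class TestRoiClusteringAndQuantize:
    def setup_scene(self):
        img = GrayscaleImage(
            np.array([[230, 230, 26], [10, 10, 10]], dtype=np.uint8)
        )
        roi = RoiMask(BinaryImage(np.array([[1, 1, 1], [0, 0, 0]], dtype=np.uint8)))
        return img, roi

    def test_non_roi_pixels_carry_sentinel(self):
        img, roi = self.setup_scene()
        assign, _ = cluster_roi(img, roi, FuzzyARTParams(rho=0.5, alpha=1.0))
        assert (assign.labels[1, :] == NON_ROI).all()
        assert (assign.labels[0, :] >= 0).all()

    def test_prototype_rounding_half_up(self):
        # traced example: weights 0.9 and 0.1 scale to 229.5 -> 230 and
        # 25.5 -> 26 under round-half-up
        assign = ClusterAssignment(
            labels=np.array([[0, 0, 1]]),
            prototypes=np.array([230, 26], dtype=np.uint8),
        )
        img = GrayscaleImage(np.array([[229, 229, 25]], dtype=np.uint8))
        roi = RoiMask(BinaryImage(np.ones((1, 3), dtype=np.uint8)))
        out = quantize(img, roi, assign)
        np.testing.assert_array_equal(out.pixels, [[230, 230, 26]])

    def test_quantize_end_to_end_from_traced_weights(self):
        img, roi = self.setup_scene()
        # normalized inputs approx [0.902, 0.902, 0.102]
        assign, state = cluster_roi(img, roi, FuzzyARTParams(rho=0.5, alpha=1.0))
        assert assign.n_clusters == 2
        out = quantize(img, roi, assign)
        assert set(np.unique(out.pixels)) <= set(assign.prototypes) | {0}
        assert (out.pixels[1, :] == 0).all()

    def test_single_cluster_quantizes_to_constant_roi(self):
        img = GrayscaleImage(np.full((3, 3), 200, dtype=np.uint8))
        roi = RoiMask(BinaryImage(np.ones((3, 3), dtype=np.uint8)))
        assign, state = cluster_roi(img, roi, FuzzyARTParams(rho=0.7))
        assert state.n_clusters == 1
        out = quantize(img, roi, assign)
        assert (out.pixels == assign.prototypes[0]).all()
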