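"""PRD, RMSE and discrete Frechet distance, against independent oracles."""

import numpy as np
import pytest

from ecggan import (
    CurvePoint,
    DegenerateInputError,
    ShapeError,
    ValidationError,
    discrete_frechet,
    discrete_frechet_bruteforce,
    evaluate_generated,
    minmax_normalize,
    prd,
    rmse,
    to_curve,
)


class TestPRD:
    def test_identical_sequences_score_zero(self, rng):
        x = rng.normal(size=10)
        assert prd(x, x) == 0.0

    def test_unit_error_full_energy(self):
        # sum sq error 1, signal energy 1 -> standard 100, as-printed sqrt(100)=10
        assert prd([1.0, 0.0], [0.0, 0.0]) == pytest.approx(100.0)
        assert prd([1.0, 0.0], [0.0, 0.0], mode="as_printed") == pytest.approx(10.0)

    def test_matches_scalar_arithmetic_oracle(self, rng):
        x = rng.normal(size=5)
        xhat = rng.normal(size=5)
        num = sum((a - b) ** 2 for a, b in zip(x, xhat))
        den = sum(a ** 2 for a in x)
        assert prd(x, xhat) == pytest.approx(100.0 * (num / den) ** 0.5, rel=1e-12)
        assert prd(x, xhat, mode="as_printed") == pytest.approx(
            (100.0 * num / den) ** 0.5, rel=1e-12
        )

    def test_scale_invariance_of_default_mode(self, rng):
        x = rng.normal(size=8)
        xhat = rng.normal(size=8)
        assert prd(3.7 * x, 3.7 * xhat) == pytest.approx(prd(x, xhat), rel=1e-10)

    def test_zero_energy_reference_rejected(self):
        with pytest.raises(DegenerateInputError):
            prd([0.0, 0.0], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            prd([1.0, 2.0], [1.0])


class TestRMSE:
    def test_identical_sequences_score_zero(self, rng):
        x = rng.normal(size=10)
        assert rmse(x, x) == 0.0

    @pytest.mark.parametrize(
        "x,xhat,expected",
        [([0.0, 0.0], [1.0, 1.0], 1.0), ([0.0, 2.0], [0.0, 0.0], np.sqrt(2.0))],
    )
    def test_hand_computed_values(self, x, xhat, expected):
        assert rmse(x, xhat) == pytest.approx(expected)

    def test_translation_invariance(self, rng):
        x = rng.normal(size=8)
        xhat = rng.normal(size=8)
        assert rmse(x + 5.0, xhat + 5.0) == pytest.approx(rmse(x, xhat), rel=1e-12)

    def test_matches_scalar_arithmetic_oracle(self, rng):
        x = rng.normal(size=4)
        xhat = rng.normal(size=4)
        expected = (sum((a - b) ** 2 for a, b in zip(x, xhat)) / 4) ** 0.5
        assert rmse(x, xhat) == pytest.approx(expected, rel=1e-12)


class TestDiscreteFrechet:
    def test_identity_is_zero(self, rng):
        P = rng.normal(size=(7, 2))
        assert discrete_frechet(P, P) == 0.0

    def test_single_point_pair_is_euclidean_distance(self):
        assert discrete_frechet([(0.0, 0.0)], [(3.0, 4.0)]) == pytest.approx(5.0)

    def test_accepts_curvepoint_lists(self):
        P = [CurvePoint(0.0, 0.0), CurvePoint(1.0, 1.0)]
        Q = [CurvePoint(0.0, 1.0), CurvePoint(1.0, 0.0)]
        assert discrete_frechet(P, Q) == pytest.approx(1.0)

    def test_dp_equals_bruteforce_on_random_small_curves(self, rng):
        """DP equals exhaustive monotone-coupling enumeration for 500
        random integer-coordinate curve pairs of up to 6 points."""
        for _ in range(500):
            n, m = rng.integers(1, 7, size=2)
            P = rng.integers(-5, 6, size=(n, 2)).astype(float)
            Q = rng.integers(-5, 6, size=(m, 2)).astype(float)
            dp = discrete_frechet(P, Q)
            assert dp == pytest.approx(discrete_frechet_bruteforce(P, Q), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(50):
            P = rng.normal(size=(rng.integers(1, 8), 2))
            Q = rng.normal(size=(rng.integers(1, 8), 2))
            assert discrete_frechet(P, Q) == pytest.approx(
                discrete_frechet(Q, P), abs=1e-12
            )

    def test_endpoint_lower_bound(self, rng):
        """Endpoints must be coupled, so FD >= max of their distances."""
        for _ in range(50):
            P = rng.normal(size=(rng.integers(2, 8), 2))
            Q = rng.normal(size=(rng.integers(2, 8), 2))
            bound = max(
                np.linalg.norm(P[0] - Q[0]), np.linalg.norm(P[-1] - Q[-1])
            )
            assert discrete_frechet(P, Q) >= bound - 1e-12

    def test_value_only_1d_mode(self):
        # bare sequences are treated as 1-D points
        assert discrete_frechet([0.0, 1.0], [0.0, 3.0]) == pytest.approx(2.0)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValidationError):
            discrete_frechet([], [(0.0, 0.0)])


class TestToCurve:
    def test_time_axis_normalized(self):
        curve = to_curve([5.0, 6.0, 7.0])
        np.testing.assert_allclose(curve[:, 0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(curve[:, 1], [5.0, 6.0, 7.0])

    def test_single_point(self):
        assert to_curve([2.0]).tolist() == [[0.0, 2.0]]


class TestEvaluateGenerated:
    def test_self_evaluation_is_all_zero(self, window_array):
        report = evaluate_generated(window_array, window_array, pairing="fixed")
        assert report.prd == pytest.approx(0.0, abs=1e-9)
        assert report.rmse == pytest.approx(0.0, abs=1e-9)
        assert report.fd == pytest.approx(0.0, abs=1e-9)
        assert report.n_pairs == len(window_array)

    def test_single_pair_report_equals_individual_metrics(self, rng):
        real = rng.normal(size=30)
        gen = rng.normal(size=30)
        report = evaluate_generated([real], [gen], pairing="fixed")
        r = minmax_normalize(real)
        g = minmax_normalize(gen)
        assert report.prd == pytest.approx(prd(r, g))
        assert report.rmse == pytest.approx(rmse(r, g))
        assert report.fd == pytest.approx(
            discrete_frechet(to_curve(r), to_curve(g))
        )

    def test_best_match_never_worse_than_fixed(self, rng):
        for _ in range(10):
            real = [rng.normal(size=20) for _ in range(4)]
            gen = [rng.normal(size=20) for _ in range(4)]
            best = evaluate_generated(real, gen, pairing="best")
            fixed = evaluate_generated(real, gen, pairing="fixed")
            assert best.rmse <= fixed.rmse + 1e-12

    def test_pair_order_invariance_of_fixed_means(self, rng):
        real = [rng.normal(size=15) for _ in range(5)]
        gen = [rng.normal(size=15) for _ in range(5)]
        base = evaluate_generated(real, gen, pairing="fixed")
        perm = list(rng.permutation(5))
        shuffled = evaluate_generated(
            [real[i] for i in perm], [gen[i] for i in perm], pairing="fixed"
        )
        assert shuffled.prd == pytest.approx(base.prd)
        assert shuffled.rmse == pytest.approx(base.rmse)
        assert shuffled.fd == pytest.approx(base.fd)

    def test_truncation_to_shorter(self, rng):
        real = [rng.normal(size=25)]
        gen = [rng.normal(size=40)]
        report = evaluate_generated(real, gen, pairing="fixed")
        assert report.n_pairs == 1  # succeeded on the common 25-sample prefix

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_generated([], [np.ones(5)])
        with pytest.raises(ValidationError):
            evaluate_generated([np.ones(5)], [], pairing="fixed")

    def test_unknown_pairing_rejected(self, rng):
        with pytest.raises(ValidationError):
            evaluate_generated([rng.normal(size=5)], [rng.normal(size=5)], pairing="greedy")
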