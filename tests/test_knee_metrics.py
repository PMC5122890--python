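import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moeanet as mn
from moeanet.knee_metrics import (
    _assigned_angles,
    aupr,
    auroc,
    confusion_rates,
    knee_point,
    map_back,
    normalize_front,
    prune_front,
    select_knee,
    smooth_and_resample,
)
from moeanet.moea_core import CandidateSolution, ParetoFront


def front_from_points(points):
    return ParetoFront([CandidateSolution(np.zeros(2), float(x), float(y))
                        for x, y in points])


class TestPruneFront:
    def test_small_front_never_empties(self):
        front = front_from_points([(0, 3), (1, 2), (2, 1)])
        survivors = prune_front(front, k=10)
        assert len(survivors) == 1
        assert survivors.solutions[0].f1 == 0  # smallest error survives

    def test_removes_largest_error_members(self):
        rng = np.random.default_rng(0)
        f1 = rng.permutation(30).astype(float)
        front = front_from_points([(v, 30 - v) for v in f1])
        survivors = prune_front(front, k=10)
        assert len(survivors) == 20
        kept = {s.f1 for s in survivors.solutions}
        assert max(kept) < min(set(f1) - kept)

    def test_k_zero_is_identity(self):
        front = front_from_points([(0, 1), (1, 0)])
        assert len(prune_front(front, k=0)) == 2


class TestNormalizeFront:
    def test_direct_scaling(self):
        got = normalize_front(np.array([[2.0, 4.0], [4.0, 2.0]]))
        assert got.tolist() == [[0.5, 1.0], [1.0, 0.5]]

    def test_singleton_maps_to_unit_corner(self):
        assert normalize_front(np.array([[3.0, 7.0]])).tolist() == [[1.0, 1.0]]

    def test_degenerate_axis_passes_through(self):
        got = normalize_front(np.array([[0.0, 2.0], [0.0, 4.0]]))
        assert got[:, 0].tolist() == [0.0, 0.0]
        assert got[:, 1].tolist() == [0.5, 1.0]


class TestSmoothAndResample:
    def test_line_resamples_to_line(self):
        x = np.linspace(0, 1, 10)
        pts = np.column_stack([x, 1 - x])
        out = smooth_and_resample(pts, n_samples=50)
        assert np.allclose(out[:, 0] + out[:, 1], 1.0, atol=1e-6)

    def test_even_arc_length_spacing(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.random(15))
        pts = np.column_stack([x, np.exp(-3 * x)])
        out = smooth_and_resample(pts, n_samples=80)
        seg = np.hypot(*np.diff(out, axis=0).T)
        assert np.std(seg) / np.mean(seg) < 0.1

    def test_interpolates_evenly_spaced_inputs(self):
        x = np.linspace(0, 1, 8)
        pts = np.column_stack([x, 1 - x])
        out = smooth_and_resample(pts, n_samples=8, smoothing=0.0)
        assert np.allclose(out, pts, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_and_resample(np.array([[0.0, 1.0]]))


class TestKneePoint:
    def test_l_shaped_front_knee_at_bend(self):
        pts = normalize_front(np.array([[0.0, 1.0], [0.05, 0.05], [1.0, 0.0]]))
        resampled = smooth_and_resample(pts, n_samples=100)
        idx, angles = knee_point(resampled)
        assert map_back(resampled, idx, pts) == 1

    def test_angles_match_direct_arithmetic(self):
        # right-angle corner at the 10th of 21 points, step=1 neighbor geometry
        pts = np.array([[0.0, y] for y in np.linspace(1.0, 0.0, 11)]
                       + [[x, 0.0] for x in np.linspace(0.1, 1.0, 10)])
        angles = _assigned_angles(pts, step=1)

        def vertex_angle(i, dl, dr):
            va, vb = pts[i - dl] - pts[i], pts[i + dr] - pts[i]
            return np.arccos(np.clip(va @ vb / np.linalg.norm(va) / np.linalg.norm(vb),
                                     -1, 1))

        for i in range(2, len(pts) - 2):
            want = max(vertex_angle(i, dl, dr) for dl in (1, 2) for dr in (1, 2))
            assert angles[i] == pytest.approx(want, abs=1e-12)
        # sharpest assigned angle sits at the corner
        assert np.nanargmin(angles) == 10

    def test_straight_front_ties_resolve_to_smallest_error(self):
        front = front_from_points([(x, 1 - x) for x in np.linspace(0, 1, 20)])
        sel = select_knee(front, prune_k=0)
        assert sel.chosen == 0
        assert sel.front.solutions[sel.chosen].f1 == 0.0

    def test_needs_five_points(self):
        with pytest.raises(ValueError):
            knee_point(np.zeros((4, 2)))


class TestSelectKnee:
    def test_chosen_always_indexes_surviving_member(self, small_system, fast_moea):
        front = mn.run_moeanet(small_system, fast_moea)
        sel = select_knee(front)
        assert 0 <= sel.chosen < len(sel.front)
        assert sel.solution is sel.front.solutions[sel.chosen]
        assert len(sel.front) + len(sel.pruned) == len(front)

    def test_tiny_front_falls_back_to_min_error(self):
        front = front_from_points([(0.1, 2.0), (3.0, 0.5)])
        sel = select_knee(front, prune_k=0)
        assert sel.front.solutions[sel.chosen].f1 == 0.1

    def test_sharp_knee_detected_on_synthetic_front(self):
        pts = ([(0.001 * (1 - y), y) for y in np.linspace(1.0, 0.1, 15)]
               + [(x, 0.1 - 0.05 * x) for x in np.linspace(0.1, 1.0, 15)])
        sel = select_knee(front_from_points(pts), prune_k=0)
        corner = sel.front.solutions[sel.chosen]
        assert corner.f1 < 0.2 and corner.f2 < 0.2  # near the bend


class TestReconstructionError:
    def test_perfect_recovery_is_zero(self, small_net):
        assert mn.reconstruction_error(small_net.adjacency, small_net.adjacency) == 0.0

    def test_all_zero_estimate_scores_one(self, small_net):
        X0 = np.zeros_like(small_net.adjacency)
        assert mn.reconstruction_error(X0, small_net.adjacency) == pytest.approx(1.0)

    def test_single_edge_hand_value(self):
        X_true = np.zeros((2, 2))
        X_true[0, 1] = X_true[1, 0] = 2.0
        X_est = np.zeros((2, 2))
        X_est[0, 1] = X_est[1, 0] = 1.5
        assert mn.reconstruction_error(X_est, X_true) == pytest.approx(0.25)

    def test_all_zero_truth_undefined(self):
        with pytest.raises(ValueError):
            mn.reconstruction_error(np.zeros((3, 3)), np.zeros((3, 3)))

    @given(st.floats(0.1, 50.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        X_true = rng.uniform(1, 3, (4, 4))
        np.fill_diagonal(X_true, 0)
        X_true = (X_true + X_true.T) / 2
        X_est = X_true * 1.1
        base = mn.reconstruction_error(X_est, X_true)
        assert mn.reconstruction_error(c * X_est, c * X_true) == pytest.approx(base)


class TestConfusionRates:
    def test_perfect_reconstruction(self, small_net):
        tpr, fpr, precision = confusion_rates(small_net.adjacency, small_net.adjacency)
        assert (tpr, fpr, precision) == (1.0, 0.0, 1.0)

    def test_empty_estimate(self, small_net):
        tpr, fpr, precision = confusion_rates(np.zeros_like(small_net.adjacency),
                                              small_net.adjacency)
        assert (tpr, fpr, precision) == (0.0, 0.0, 1.0)

    def test_hand_counted_case(self):
        # 4 nodes: edges (0,1), (2,3) true; estimate finds both plus spurious (0,2)
        X_true = np.zeros((4, 4))
        for i, j in [(0, 1), (2, 3)]:
            X_true[i, j] = X_true[j, i] = 2.0
        X_est = X_true.copy()
        X_est[0, 2] = X_est[2, 0] = 0.9
        tpr, fpr, precision = confusion_rates(X_est, X_true)
        assert tpr == 1.0
        assert fpr == pytest.approx(0.25)
        assert precision == pytest.approx(2 / 3)


class TestRankingAreas:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0
        assert aupr([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_single_discordant_pair(self):
        assert auroc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    def test_inverted_scores(self):
        assert auroc([0.1, 0.9], [1, 0]) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])
        with pytest.raises(ValueError):
            aupr([0.1, 0.9], [0, 0])

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        base = auroc(scores, labels)
        assert auroc(np.exp(5 * scores), labels) == pytest.approx(base)
        assert auroc(scores ** 3, labels) == pytest.approx(base)
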