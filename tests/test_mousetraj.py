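"""Unit tests for trajectory preprocessing, metrics and macro-states."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from cogflex import mousetraj as mt


def make_raw(x, y, dt=10.0, **meta):
    t = np.arange(len(x)) * dt
    return mt.RawTrajectory(t, np.asarray(x, float), np.asarray(y, float),
                            meta)


class TestExtractMotion:
    def test_leading_duplicates_collapse(self):
        raw = make_raw([0, 0, 0, 1, 2], [0, 0, 0, 1, 2])
        out = mt.extract_motion(raw)
        assert len(out.x) == 3  # first sample + the two moving ones

    def test_both_vs_either_mode(self):
        raw = make_raw([0, 1, 2], [0, 0, 1])  # second step: only x moved
        both = mt.extract_motion(raw, mode="both")
        either = mt.extract_motion(raw, mode="either")
        assert len(both.x) == 2
        assert len(either.x) == 3

    def test_stationary_trace_errors(self):
        with pytest.raises(ValueError, match="motion"):
            mt.extract_motion(make_raw([1, 1, 1], [2, 2, 2]))


class TestTimeNormalize:
    def test_output_length(self):
        raw = make_raw(np.arange(37), np.arange(37) ** 2)
        out = mt.time_normalize(raw)
        assert len(out.x) == 101

    def test_linear_path_exact(self):
        raw = make_raw(np.linspace(0, 5, 7), np.linspace(2, 9, 7))
        out = mt.time_normalize(raw)
        np.testing.assert_allclose(out.x, np.linspace(0, 5, 101), atol=1e-12)
        np.testing.assert_allclose(out.y, np.linspace(2, 9, 101), atol=1e-12)

    def test_endpoints_preserved(self, rng):
        raw = make_raw(rng.normal(size=60).cumsum() + 5,
                       rng.normal(size=60).cumsum())
        out = mt.time_normalize(raw)
        assert out.x[0] == raw.x[0] and out.x[-1] == raw.x[-1]


class TestSpatialAlign:
    def test_affine_hand_example(self):
        raw = mt.RawTrajectory(np.linspace(0, 100, 101),
                               np.linspace(5, 15, 101),
                               np.linspace(-3, 7, 101))
        out = mt.spatial_align(raw)
        np.testing.assert_allclose(out.x[[0, 50, 100]], [0, 0.5, 1],
                                   atol=1e-12)
        np.testing.assert_allclose(out.y[[0, -1]], [0, 1], atol=1e-12)

    def test_idempotent(self, rng):
        raw = make_raw(np.linspace(0, 3, 101) + rng.normal(0, 0.01, 101),
                       np.linspace(0, 2, 101) + rng.normal(0, 0.01, 101))
        once = mt.spatial_align(mt.time_normalize(raw))
        twice = mt.spatial_align(
            mt.RawTrajectory(np.arange(101.0), once.x, once.y, once.meta))
        np.testing.assert_allclose(once.x, twice.x, atol=1e-12)
        np.testing.assert_allclose(once.y, twice.y, atol=1e-12)

    def test_degenerate_coordinate_errors(self):
        raw = make_raw(np.r_[np.linspace(0, 1, 100), 0.0], np.arange(101.0))
        with pytest.raises(ValueError, match="degenerate"):
            mt.spatial_align(raw)


class TestAUC:
    def test_straight_line_zero(self):
        d = np.linspace(0, 1, 101)
        assert mt.auc(mt.NormalizedTrajectory(d, d)) == pytest.approx(0.0)

    def test_corner_path_half(self):
        x = np.concatenate([np.linspace(0, 1, 51), np.ones(50)])
        y = np.concatenate([np.zeros(51), np.linspace(0, 1, 51)[1:]])
        assert mt.auc(mt.NormalizedTrajectory(x, y)) == pytest.approx(0.5)

    def test_reflection_invariance(self, rng):
        x = np.linspace(0, 1, 101)
        y = np.clip(x + rng.normal(0, 0.05, 101), 0, 1)
        y[0], y[-1] = 0.0, 1.0
        a = mt.auc(mt.NormalizedTrajectory(x, y))
        b = mt.auc(mt.NormalizedTrajectory(y, x))  # mirror across diagonal
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_fine_grid_integration(self, rng):
        """Shoelace area equals numerical integration of the perpendicular
        offset for paths monotone along the diagonal."""
        for _ in range(20):
            n = int(rng.integers(5, 30))
            s = np.sort(rng.uniform(0, 1, n))
            s[0], s[-1] = 0.0, 1.0
            off = rng.normal(0, 0.1, n)
            off[0] = off[-1] = 0.0
            x = s - off / 2
            y = s + off / 2
            grid101 = np.linspace(0, 1, 101)
            base = np.linspace(0, 1, n)
            traj = mt.NormalizedTrajectory(np.interp(grid101, base, x),
                                           np.interp(grid101, base, y))
            signed = mt.auc(traj, signed=True)
            # oracle: integrate the perpendicular offset along the diagonal
            # in the rotated frame (area is rotation-invariant)
            grid = np.linspace(0, 1, 20001)
            xi = np.interp(grid, grid101, traj.x)
            yi = np.interp(grid, grid101, traj.y)
            u = (xi + yi) / np.sqrt(2)
            v = (yi - xi) / np.sqrt(2)
            oracle = np.trapezoid(v, u)
            assert abs(signed) == pytest.approx(abs(oracle), abs=1e-6)
            assert mt.auc(traj) == pytest.approx(abs(oracle), abs=1e-6)


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        assert mt.permutation_entropy(np.arange(50), m=5) == pytest.approx(0.0)

    def test_hand_enumeration_m2(self):
        # patterns: up, down, up, down, up -> p = (0.6, 0.4)
        h = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4)) / math.log(2)
        assert mt.permutation_entropy([1, 3, 2, 4, 3, 5], m=2) == \
            pytest.approx(h, abs=1e-12)

    def test_iid_series_near_maximal(self, rng):
        s = rng.uniform(size=10_000)
        assert mt.permutation_entropy(s, m=3) == pytest.approx(1.0, abs=0.02)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            mt.permutation_entropy([1, 2, 3], m=5)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_matches_exhaustive_pattern_counting(self, rng, m):
        """PE equals an independent ordinal-pattern count with the same
        stable tie-breaking, on random short series (with ties)."""
        for _ in range(30):
            n = int(rng.integers(m + 1, 50))
            s = rng.integers(0, 6, size=n).astype(float)  # ties likely
            counts = Counter()
            for start in range(n - m + 1):
                w = s[start:start + m]
                pattern = tuple(sorted(range(m), key=lambda i: (w[i], i)))
                counts[pattern] += 1
            p = np.array(list(counts.values())) / (n - m + 1)
            h = -(p * np.log(p)).sum() / math.log(math.factorial(m))
            assert mt.permutation_entropy(s, m=m) == pytest.approx(h,
                                                                   abs=1e-12)


class TestDeviationsAndKinematics:
    def test_direction_change_conventions(self):
        assert mt.count_deviations(np.arange(10)) == 0
        assert mt.count_deviations([0, 1, 0, 1]) == 2
        assert mt.count_deviations([0, 1, 1, 0]) == 1

    def test_path_length_and_velocity(self):
        d = np.linspace(0, 1, 101)
        tr = mt.NormalizedTrajectory(d, d, {"duration_ms": 500.0})
        ed, v = mt.kinematics(tr)
        assert ed == pytest.approx(np.sqrt(2))
        assert v == pytest.approx(np.sqrt(2) / 500)
        ed2, v2 = mt.kinematics(tr, duration_ms=250.0)
        assert v2 == pytest.approx(2 * v)

    def test_ed_at_least_endpoint_distance(self, rng):
        x = np.linspace(0, 1, 101) + rng.normal(0, 0.03, 101)
        y = np.linspace(0, 1, 101) + rng.normal(0, 0.03, 101)
        tr = mt.NormalizedTrajectory(x, y, {"duration_ms": 1000.0})
        ed, _ = mt.kinematics(tr)
        assert ed >= np.hypot(x[-1] - x[0], y[-1] - y[0])

    def test_zero_duration_errors(self):
        d = np.linspace(0, 1, 101)
        with pytest.raises(ValueError):
            mt.kinematics(mt.NormalizedTrajectory(d, d), duration_ms=0.0)


def blob_trajectories(rng, n_participants=3, trials_per=6):
    """Trajectories visiting 4 well-separated Gaussian blobs in order."""
    centers = np.array([[0, 0], [0.4, 0.35], [0.7, 0.75], [1, 1]])
    out = []
    for p in range(n_participants):
        for _ in range(trials_per):
            pts = np.vstack([
                rng.normal(c, 0.03, size=(26, 2)) for c in centers
            ])[:101]
            out.append(mt.NormalizedTrajectory(
                pts[:, 0], pts[:, 1],
                {"participant_id": f"p{p}", "duration_ms": 1000.0}))
    return out


class TestStateModel:
    def test_needs_two_participants(self, rng):
        trajs = blob_trajectories(rng, n_participants=1)
        with pytest.raises(ValueError, match="participants"):
            mt.TrajectoryStateModel().fit(trajs)

    def test_recovers_four_blobs_with_semantic_labels(self, rng):
        trajs = blob_trajectories(rng)
        model = mt.fit_state_model(trajs, seed=0)
        assert model.k == 4
        assert set(model.label_map.values()) == set(mt.STATE_NAMES)
        # clusters ordered by mean time index: first points -> Initiation
        seq = mt.state_sequence(trajs[0], model)
        assert model.label_map[seq[0]] == "Initiation"
        assert model.label_map[seq[-1]] == "Termination"

    def test_aic_parameter_count_k2(self, rng):
        """AIC = 2 p - 2 logL with p = 11 for k=2 full-covariance 2-D."""
        from sklearn.mixture import GaussianMixture
        X = np.vstack([rng.normal(0, 1, (200, 2)),
                       rng.normal(5, 1, (200, 2))])
        g = GaussianMixture(2, covariance_type="full",
                            random_state=0).fit(X)
        expected = 2 * 11 - 2 * g.score(X) * len(X)
        assert g.aic(X) == pytest.approx(expected, rel=1e-10)

    def test_deterministic_given_seed(self, rng):
        trajs = blob_trajectories(rng)
        m1 = mt.fit_state_model(trajs, k_range=(3, 4, 5), seed=7)
        m2 = mt.fit_state_model(trajs, k_range=(3, 4, 5), seed=7)
        assert m1.k == m2.k
        np.testing.assert_allclose(m1.means, m2.means)

    def test_point_at_cluster_mean_assigned_there(self, rng):
        trajs = blob_trajectories(rng)
        model = mt.fit_state_model(trajs, k_range=(4,), seed=0)
        for c in range(4):
            probe = np.tile(model.means[c], (101, 1))
            tr = mt.NormalizedTrajectory(probe[:, 0], probe[:, 1], {})
            labels = mt.state_sequence(tr, model)
            assert np.all(labels == c)


class TestStateSummaries:
    def test_transition_matrix_hand_count(self):
        tm = mt.transition_matrix([np.array([0, 0, 1, 1])], k=2)
        np.testing.assert_allclose(tm, [[0.5, 0.5], [0.0, 1.0]])

    def test_constant_sequence_identity_row(self):
        tm = mt.transition_matrix([np.zeros(10, int)], k=2)
        np.testing.assert_allclose(tm[0], [1.0, 0.0])
        assert tm[1].sum() == 0.0  # flagged: no outgoing transitions

    def test_dwell_time_hand_examples(self):
        dt = mt.dwell_time([np.array([0, 0, 0, 1, 1])], k=2)
        np.testing.assert_allclose(dt, [3.0, 2.0])
        dt = mt.dwell_time([np.array([0, 1, 0, 1])], k=2)
        np.testing.assert_allclose(dt, [1.0, 1.0])

    def test_dwell_time_relabeling_permutes(self):
        seq = np.array([0, 0, 1, 2, 2, 2])
        dt = mt.dwell_time([seq], k=3)
        perm = np.array([2, 0, 1])  # relabel states
        dt_perm = mt.dwell_time([perm[seq]], k=3)
        for s in range(3):
            assert dt[s] == dt_perm[perm[s]]

    def test_absent_state_not_counted_as_zero(self):
        dt = mt.dwell_time([np.array([0, 0]), np.array([0, 1, 1])], k=2)
        np.testing.assert_allclose(dt, [1.5, 2.0])
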