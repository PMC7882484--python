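import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothtaxis import ClassifyConfig
from mothtaxis.maneuvers import (
    EXCLUDED, MATCH, MISMATCH, ROTATE, STOP, SURGE, blank_durations,
    classify_kinematic, classify_temporal, classify_trajectory, cohort_matrix,
    maneuver_matrix, match_labels, pose_velocities,
)


class TestBlankDurations:
    def test_single_hit_at_start(self):
        t = np.arange(5) * 0.05
        hits = np.array([1, 0, 0, 0, 0], dtype=bool)
        np.testing.assert_allclose(blank_durations(t, hits),
                                   [0.0, 0.05, 0.10, 0.15, 0.20])

    def test_no_hits_all_undefined(self):
        t = np.arange(4) * 0.05
        tau = blank_durations(t, np.zeros(4, dtype=bool))
        assert np.isnan(tau).all()

    def test_hits_every_sample_zero(self):
        t = np.arange(6) * 0.05
        tau = blank_durations(t, np.ones(6, dtype=bool))
        np.testing.assert_allclose(tau, 0.0)

    def test_undefined_before_first_hit(self):
        t = np.arange(6) * 0.05
        hits = np.array([0, 0, 1, 0, 0, 1], dtype=bool)
        tau = blank_durations(t, hits)
        assert np.isnan(tau[:2]).all()
        np.testing.assert_allclose(tau[2:], [0.0, 0.05, 0.10, 0.0])


class TestTemporalScheme:
    @pytest.mark.parametrize("tau_b,label", [
        (0.0, SURGE), (0.3, SURGE), (0.5, SURGE),  # inclusive 500 ms bound
        (0.500001, ROTATE), (0.6, ROTATE), (10.0, ROTATE),
        (float("nan"), STOP),
    ])
    def test_labels(self, tau_b, label):
        assert classify_temporal(tau_b) == label


class TestKinematicScheme:
    @pytest.mark.parametrize("tau_b,v,omega,label", [
        # clause 1: recent hit and moving forward
        (0.3, 10.0, 50.0, SURGE),
        (0.5, 0.1, 200.0, SURGE),          # boundary tau_b = 0.5 inclusive
        # clause 2: rotation past the 200 ms blank bound
        (0.3, 0.0, 100.0, ROTATE),          # stationary rotation in 0.2-0.5 s
        (0.6, 0.0, 30.0, ROTATE),
        (0.6, 0.0, 4.0, ROTATE),            # |omega| > 0 beats slow-surge clause
        (0.21, 0.0, 5.0, ROTATE),
        # clause 3: slow drift with essentially no rotation
        (0.6, 0.0, 0.0, SURGE),
        (0.3, 0.0, 0.0, SURGE),
        # clause 4: stop
        (0.2, 0.0, 100.0, STOP),            # boundary: rotate needs tau_b > 0.2
        (0.1, 0.0, 0.0, STOP),
        (float("nan"), 10.0, 10.0, STOP),
    ])
    def test_clause_order(self, tau_b, v, omega, label):
        assert classify_kinematic(tau_b, v, omega) == label

    def test_min_speed_deadband(self):
        cfg = ClassifyConfig(min_speed=1.0)
        assert classify_kinematic(0.3, 0.5, 50.0, cfg) == ROTATE
        assert classify_kinematic(0.3, 1.5, 50.0, cfg) == SURGE

    @settings(derandomize=True, max_examples=500)
    @given(
        st.one_of(st.just(float("nan")),
                  st.floats(0.0, 5.0),
                  st.sampled_from([0.2, 0.5])),
        st.floats(0.0, 50.0),
        st.one_of(st.floats(-200.0, 200.0), st.sampled_from([-5.0, 0.0, 5.0])),
    )
    def test_totality_exactly_one_label(self, tau_b, v, omega):
        for scheme in (classify_temporal(tau_b),
                       classify_kinematic(tau_b, v, omega)):
            assert scheme in (SURGE, ROTATE, STOP)


class TestMatchLabels:
    @pytest.mark.parametrize("temporal,kinematic,status", [
        (SURGE, SURGE, MATCH),
        (ROTATE, ROTATE, MATCH),
        (SURGE, ROTATE, MISMATCH),
        (ROTATE, SURGE, EXCLUDED),
        (STOP, STOP, EXCLUDED),
        (STOP, SURGE, EXCLUDED),
        (SURGE, STOP, EXCLUDED),
    ])
    def test_status(self, temporal, kinematic, status):
        assert match_labels(temporal, kinematic) == status


class TestManeuverMatrix:
    def make_records(self, pairs):
        return pd.DataFrame({
            "t": np.arange(len(pairs)) * 0.05,
            "temporal": [p[1] for p in pairs],
            "kinematic": [p[0] for p in pairs],
            "match": [match_labels(p[1], p[0]) for p in pairs],
        })

    def test_all_surge_surge(self):
        m = maneuver_matrix(self.make_records([(SURGE, SURGE)] * 10))
        np.testing.assert_allclose(m.cells, [[1.0, 0.0], [0.0, 0.0]])
        assert m.excluded_fraction == 0.0

    def test_counting_example(self):
        pairs = [(ROTATE, SURGE)] * 2 + [(ROTATE, ROTATE)] * 8
        m = maneuver_matrix(self.make_records(pairs))
        assert m.cell(ROTATE, SURGE) == pytest.approx(0.2)
        assert m.cell(ROTATE, ROTATE) == pytest.approx(0.8)

    def test_cells_plus_excluded_sum_to_one(self):
        pairs = ([(SURGE, SURGE)] * 3 + [(ROTATE, SURGE)] * 2
                 + [(ROTATE, ROTATE)] * 4 + [(STOP, STOP)] * 3)
        m = maneuver_matrix(self.make_records(pairs))
        assert m.cells.sum() + m.excluded_fraction == pytest.approx(1.0, abs=1e-12)

    def test_empty_and_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            maneuver_matrix(self.make_records([]))
        with pytest.raises(ValueError):
            maneuver_matrix(self.make_records([(STOP, STOP)] * 4))

    def test_cohort_mean_sd(self):
        m1 = maneuver_matrix(self.make_records([(SURGE, SURGE)] * 10))
        m2 = maneuver_matrix(self.make_records(
            [(SURGE, SURGE)] * 5 + [(ROTATE, ROTATE)] * 5))
        cm = cohort_matrix([m1, m2])
        assert cm["mean"][0, 0] == pytest.approx(0.75)
        assert cm["n_trials"] == 2


class TestPoseVelocities:
    def test_constant_speed_straight_segment(self):
        t = np.arange(50) * 0.05
        x = 100.0 - 24.0 * t
        y = np.zeros_like(t)
        theta = np.full_like(t, math.pi)
        v, omega = pose_velocities(t, x, y, theta)
        np.testing.assert_allclose(v[1:-1], 24.0, rtol=0.01)
        np.testing.assert_allclose(omega[1:-1], 0.0, atol=1e-9)

    def test_constant_turn_rate(self):
        t = np.arange(50) * 0.05
        w = math.radians(60.0)
        theta = np.array([(-math.pi + (0.1 + w * ti)) % (2 * math.pi) - math.pi
                          for ti in t])
        v, omega = pose_velocities(t, np.zeros_like(t), np.zeros_like(t), theta)
        np.testing.assert_allclose(omega[1:-1], 60.0, rtol=0.01)


def test_classify_trajectory_velocity_consistency(arena):
    """Synthetic constant-speed surge segments come back within 1% and are
    labelled matching Surge."""
    n = 41
    t = np.arange(n) * 0.05
    x = 150.0 - 24.0 * t
    df = pd.DataFrame({"t": t, "x": x, "y": np.zeros(n),
                       "theta": np.full(n, math.pi),
                       "hit_left": np.ones(n, dtype=int),
                       "hit_right": np.zeros(n, dtype=int)})
    out = classify_trajectory(df, theta_src=arena.wind_angle)
    mid = out.iloc[1:-1]
    np.testing.assert_allclose(mid["v"], 24.0, rtol=0.01)
    assert (mid["temporal"] == SURGE).all()
    assert (mid["kinematic"] == SURGE).all()
    assert (mid["match"] == MATCH).all()
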