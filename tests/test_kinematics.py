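import numpy as np
import pandas as pd
import pytest

import rotadapt as ra
from rotadapt.kinematics import (apply_exclusions, assign_epochs, detect_bounds,
                                 movement_direction, reaction_time, summarize_experiment)
from rotadapt.synthetic_data import min_jerk_speed

from conftest import straight_reach


class TestDetectBounds:
    def test_threshold_crossings_on_piecewise_profile(self):
        # positions whose central-difference speeds are [0,0,5,10,10,5,0,0,0] cm/s:
        # onset at the first sample >= 1 (=0.1*peak), end at the first
        # post-peak sample < 1
        x = np.array([0, 0, 0, 1, 2, 3, 3, 3, 3], dtype=float)
        t = np.arange(9) * 100.0  # 10 Hz
        traj = np.column_stack([t, x, np.zeros(9)])
        onset, end, peak = detect_bounds(traj)
        assert peak == pytest.approx(10.0)
        assert onset == 200.0
        assert end == 600.0

    def test_min_jerk_bounds_match_root_finding_oracle(self):
        """Onset/end equal the roots of speed(t) = 0.1 * peak on the closed form."""
        T, A, hold = 430.0, 8.4, 300.0
        traj = straight_reach(25.0, amplitude=A, duration_ms=T, hold_ms=hold)
        onset, end, peak = detect_bounds(traj)
        # oracle: dense-grid root search on 30*A*tau^2*(1-tau)^2 / T
        tt = np.linspace(0.0, T, 2_000_001)
        sp = min_jerk_speed(tt, T, A) * 1000.0  # cm/s
        thresh = 0.1 * sp.max()
        t_on = tt[np.argmax(sp >= thresh)] + hold
        after = np.argmax(sp)
        t_off = tt[after + np.argmax(sp[after:] < thresh)] + hold
        dt = 5.0  # one sample at 200 Hz
        assert abs(onset - t_on) <= dt
        assert abs(end - t_off) <= dt
        assert peak == pytest.approx(sp.max() / 1000.0 * 1000.0, rel=0.01)

    def test_symmetric_profile_bounds_equidistant_from_peak(self):
        traj = straight_reach(0.0)
        onset, end, _ = detect_bounds(traj)
        speed_peak_t = traj[np.argmax(np.hypot(*np.gradient(traj[:, 1:3], traj[:, 0] / 1e3,
                                                            axis=0).T[:2])), 0]
        # minimum-jerk speed is symmetric about its peak
        assert abs((speed_peak_t - onset) - (end - speed_peak_t)) <= 5.0 + 1e-9

    def test_degenerate_trajectory_rejected(self):
        traj = np.column_stack([np.arange(5) * 10.0, np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="zero speed"):
            detect_bounds(traj)


class TestMovementDirection:
    def test_straight_rays(self):
        assert movement_direction(straight_reach(40.0), 40.0) == pytest.approx(0.0, abs=1e-9)
        assert movement_direction(straight_reach(50.0), 40.0) == pytest.approx(10.0, abs=1e-9)
        assert movement_direction(straight_reach(30.0), 40.0) == pytest.approx(-10.0, abs=1e-9)

    def test_curved_trajectory_matches_geometric_oracle(self):
        # spiral-ish curved path crossing the 8 cm radius
        t = np.arange(0.0, 600.0, 5.0)
        frac = t / t[-1]
        r = 9.0 * frac
        theta = np.radians(20.0 + 15.0 * frac)  # curls counterclockwise
        traj = np.column_stack([t, r * np.cos(theta), r * np.sin(theta)])
        got = movement_direction(traj, 20.0, 8.0)
        # independent oracle: locate the radius crossing and atan2 there
        rr = np.hypot(traj[:, 1], traj[:, 2])
        j = int(np.argmax(rr >= 8.0))
        lam = (8.0 - rr[j - 1]) / (rr[j] - rr[j - 1])
        x = traj[j - 1, 1] + lam * (traj[j, 1] - traj[j - 1, 1])
        y = traj[j - 1, 2] + lam * (traj[j, 2] - traj[j - 1, 2])
        expected = np.degrees(np.arctan2(y, x)) - 20.0
        assert got == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("rot", [-170.0, -45.0, 13.7, 90.0, 180.0])
    def test_rotation_equivariance(self, rot):
        """Rotating trajectory and target together leaves the direction unchanged."""
        traj = straight_reach(33.0)
        base = movement_direction(traj, 25.0)
        c, s = np.cos(np.radians(rot)), np.sin(np.radians(rot))
        rotated = traj.copy()
        rotated[:, 1] = c * traj[:, 1] - s * traj[:, 2]
        rotated[:, 2] = s * traj[:, 1] + c * traj[:, 2]
        assert movement_direction(rotated, 25.0 + rot) == pytest.approx(base, abs=1e-9)

    def test_radius_never_reached_raises(self):
        traj = straight_reach(0.0, amplitude=5.0)
        with pytest.raises(ValueError, match="never reaches"):
            movement_direction(traj, 0.0, 8.0)

    def test_matches_simulator_commanded_direction(self, default_design):
        """Noise-free simulated reaches recover the commanded direction to < 0.1 deg."""
        from rotadapt.synthetic_data import SubjectParams, simulate_subject

        p = SubjectParams(trial_noise_sd_deg=0.0)
        recs = simulate_subject(default_design, p, seed=4, trajectories=True,
                                invalid_rate=0.0)
        for r in recs[::17]:
            got = movement_direction(r.trajectory, r.target_angle_deg)
            assert abs(got - r.hand_direction_deg) < 0.1


class TestReactionTimeAndExclusions:
    def test_reaction_time_is_onset_minus_target_onset(self):
        traj = straight_reach(0.0, hold_ms=300.0)
        onset, _, _ = detect_bounds(traj)
        assert reaction_time(traj, 0.0) == onset
        assert reaction_time(traj, onset) == 0.0
        # onset before target onset yields a negative value, not a clipped zero
        assert reaction_time(traj, onset + 100.0) == -100.0

    def test_monotone_reach_valid_short_reach_excluded(self):
        assert apply_exclusions(straight_reach(0.0, amplitude=8.0)) == (True, "none")
        valid, reason = apply_exclusions(straight_reach(0.0, amplitude=7.0))
        assert (valid, reason) == (False, "short_reach")

    def test_crafted_violations_counted_exactly(self):
        trajs = [straight_reach(10.0 * k) for k in range(10)]
        # violation 1: dip in radius after passing 0.4 cm
        bad1 = trajs[3].copy()
        r = np.hypot(bad1[:, 1], bad1[:, 2])
        k = int(np.argmax(r > 2.0))
        bad1[k, 1:3] *= 0.9  # pull one sample back toward origin
        trajs[3] = bad1
        # violation 2: reach stops at 6 cm
        trajs[7] = straight_reach(70.0, amplitude=6.0)
        flags = [apply_exclusions(tr)[0] for tr in trajs]
        assert flags.count(False) == 2
        assert apply_exclusions(trajs[3])[1] == "non_monotonic"
        assert apply_exclusions(trajs[7])[1] == "short_reach"

    def test_tiny_jitter_tolerated_but_literal_rule_available(self):
        traj = straight_reach(0.0)
        r = np.hypot(traj[:, 1], traj[:, 2])
        k = int(np.argmax(r > 3.0))
        # one sample dips 0.005 cm below its predecessor: within tolerance
        traj[k, 1:3] = traj[k - 1, 1:3] * (1.0 - 0.005 / r[k - 1])
        assert apply_exclusions(traj)[0] is True
        assert apply_exclusions(traj, monotone_tol_cm=0.0)[0] is False

    def test_exclusion_fraction_on_default_experiment(self, default_design):
        """The generator injects ~1% invalid trials; exclusions land in [0.5%, 2%]."""
        gp = ra.default_group_params()
        exp = ra.simulate_experiment(default_design, gp, 2, seed=55, trajectories=True)
        kin = summarize_experiment(exp.records)
        frac = 1.0 - kin["valid"].mean()
        assert 0.005 <= frac <= 0.02
        # the 500 ms movement-time criterion flags but never excludes
        flagged = kin[kin.movement_time_flag]
        assert flagged["valid"].all() or flagged.empty


class TestAssignEpochs:
    def test_full_subject_epoch_sizes(self, small_epoched):
        one = small_epoched[small_epoched.subject_id == small_epoched.subject_id.iloc[0]]
        sizes = one["epoch"].value_counts()
        assert sizes["early_baseline"] == 40 and sizes["late_baseline"] == 40
        assert sizes["early_aftereffect"] == 20 and sizes["late_aftereffect"] == 20
        assert sizes["washout"] == 40
        adapt = sizes[sizes.index.str.startswith("adaptation_")]
        assert len(adapt) == 30 and (adapt == 8).all()
        assert sizes.sum() == 400
        assert one["trial"].is_unique  # no trial assigned twice

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["subject_id", "group", "phase", "trial",
                                      "movement_direction_deg"])
        out = assign_epochs(empty)
        assert len(out) == 0

    def test_excluded_trials_keep_label_but_shrink_model_input(self, small_experiment):
        tt = small_experiment.trial_table.assign(valid=True)
        sid = tt.subject_id.iloc[0]
        # exclude 3 adaptation trials of one subject (trials 80, 81, 88)
        mask = (tt.subject_id == sid) & tt.trial.isin([80, 81, 88])
        tt.loc[mask, "valid"] = False
        ep = assign_epochs(tt)
        assert (ep.loc[~ep["valid"], "epoch"] == ["adaptation_01", "adaptation_01",
                                                  "adaptation_02"]).all()
        kept = ep[ep["valid"] & (ep.subject_id == sid)]
        sizes = kept["epoch"].value_counts()
        assert sizes["adaptation_01"] == 6 and sizes["adaptation_02"] == 7
        assert sizes.sum() == 397

    def test_unknown_phase_rejected(self):
        bad = pd.DataFrame({"subject_id": ["a"], "group": ["g"], "phase": ["probe"],
                            "trial": [0], "movement_direction_deg": [0.0]})
        with pytest.raises(ValueError, match="unknown phase"):
            assign_epochs(bad)
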