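"""Behavioral classifiers: boundary rules, closed forms, brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberbehav import behavior as bh
from fiberbehav import synthetic
from fiberbehav.errors import DataError, ParameterError
from fiberbehav.io_formats import EventTable

FR = 30.0  # frames per second used throughout


def make_traj(x, y, motion=None, frame_rate=FR, arena=(50.0, 50.0)):
    n = len(x)
    if motion is None:
        motion = np.zeros(n)
    return bh.Trajectory(frame=np.arange(n), time=np.arange(n) / frame_rate,
                         x=np.asarray(x, float), y=np.asarray(y, float),
                         motion=np.asarray(motion, float),
                         frame_rate=frame_rate, arena=arena)


def dip_table(pairs):
    return EventTable(pd.DataFrame(
        [{"behavior": "head_dip", "start": a, "stop": b} for a, b in pairs]))


class TestVelocity:
    def test_stationary_track_all_zero(self):
        traj = make_traj(np.full(100, 25.0), np.full(100, 25.0))
        assert np.allclose(bh.velocity(traj), 0.0)

    def test_straight_line_closed_form(self):
        # 10 cm/s along x for 30 s
        n = int(30 * FR)
        traj = make_traj(10.0 / FR * np.arange(n) % 45 + 2, np.full(n, 25.0))
        # avoid the wrap: use a big arena and no modulo instead
        traj = make_traj(2 + 10.0 / FR * np.arange(n), np.full(n, 25.0),
                         arena=(400.0, 50.0))
        v = bh.velocity(traj)
        core = v[int(2 * FR):-int(2 * FR)]
        assert np.allclose(core, 10.0, rtol=0.02)

    def test_zero_window_is_raw_finite_difference(self):
        rng = np.random.default_rng(0)
        traj = make_traj(np.cumsum(rng.uniform(0, 0.2, 50)) + 10,
                         np.full(50, 25.0))
        v = bh.velocity(traj, smooth_window=0)
        expected = np.hypot(np.diff(traj.x), np.diff(traj.y)) * FR
        assert np.allclose(v[1:], expected)

    def test_single_frame_errors(self):
        traj = make_traj([1.0], [1.0])
        with pytest.raises(ParameterError):
            bh.velocity(traj)


class TestImmobility:
    def make_still(self, n):
        return make_traj(np.full(n, 25.0), np.full(n, 25.0),
                         motion=np.full(n, 0.2))

    def test_twenty_still_frames_one_bout(self):
        traj = self.make_still(20)
        bouts = bh.detect_immobility(traj)
        assert len(bouts) == 1
        assert bouts[0] == (0.0, pytest.approx(20 / FR))

    def test_fifteen_frames_is_not_enough(self):
        # the rule is bouts OVER 15 successive frames: 15 exactly fails
        traj = self.make_still(15)
        assert bh.detect_immobility(traj) == []
        traj16 = self.make_still(16)
        assert len(bh.detect_immobility(traj16)) == 1

    def test_low_speed_but_high_motion_disqualifies(self):
        # both criteria are required: slow grooming (motion 2 %) is not
        # immobility
        traj = make_traj(np.full(40, 25.0), np.full(40, 25.0),
                         motion=np.full(40, 2.0))
        assert bh.detect_immobility(traj) == []


class TestLocomotion:
    def test_continuous_run_single_bout_distance(self):
        # 10 s at 10 cm/s -> one bout of ~100 cm
        n = int(10 * FR)
        traj = make_traj(1 + 10.0 / FR * np.arange(n), np.full(n, 25.0),
                         arena=(120.0, 50.0))
        bouts, dist = bh.detect_locomotion(traj)
        assert len(bouts) == 1
        assert dist == pytest.approx(100.0, rel=0.02)

    def test_short_run_below_100mm_discarded(self):
        # ~1.3 s at 7 cm/s covers ~9 cm < the 10-cm minimum
        n_run = int(np.ceil(9.0 / 7.0 * FR))
        x = np.concatenate([np.full(60, 5.0),
                            5.0 + 7.0 / FR * np.arange(n_run),
                            np.full(60, 5.0 + 9.0)])
        traj = make_traj(x, np.full(len(x), 25.0))
        bouts, dist = bh.detect_locomotion(traj)
        assert bouts == []
        assert dist == 0.0

    def test_stationary_gives_nothing(self):
        traj = make_traj(np.full(100, 25.0), np.full(100, 25.0))
        assert bh.detect_locomotion(traj) == ([], 0.0)


class TestPauses:
    def test_two_seconds_still_then_move(self):
        n_still = int(2 * FR)
        n_move = int(3 * FR)
        x = np.concatenate([np.full(n_still, 5.0),
                            5.0 + 10.0 / FR * np.arange(n_move)])
        traj = make_traj(x, np.full(len(x), 25.0), arena=(60.0, 50.0))
        pauses, inits = bh.detect_pauses(traj)
        assert len(pauses) == 1
        assert len(inits) == 1
        assert inits[0] == pytest.approx(2.0, abs=0.5)

    def test_sub_second_slow_segment_is_no_pause(self):
        # 0.9 s below 3 cm/s fails the >= 1 s rule
        n_slow = int(0.9 * FR)
        n_move = int(3 * FR)
        seg = 10.0 / FR * np.arange(n_move)
        x = np.concatenate([5.0 + seg, 5.0 + seg[-1] + np.full(n_slow, 0.0),
                            5.0 + seg[-1] + 10.0 / FR * np.arange(n_move)])
        traj = make_traj(x, np.full(len(x), 25.0), arena=(120.0, 50.0))
        pauses, _ = bh.detect_pauses(traj, bh.velocity(traj, 0.0))
        assert pauses == []

    def test_constant_fast_speed_no_pause(self):
        n = int(10 * FR)
        traj = make_traj(1 + 10.0 / FR * np.arange(n), np.full(n, 25.0),
                         arena=(120.0, 50.0))
        pauses, inits = bh.detect_pauses(traj)
        assert pauses == [] and inits == []


class TestZones:
    def test_wall_hugging_zero_center_time(self):
        n = 300
        traj = make_traj(np.linspace(1, 49, n), np.full(n, 1.0))
        z = bh.zone_metrics(traj)
        assert z["center_time"] == 0.0
        assert z["thigmo_time"] == pytest.approx(traj.duration)

    def test_central_path_zero_thigmo_time(self):
        n = 300
        traj = make_traj(np.linspace(20, 30, n), np.full(n, 25.0))
        z = bh.zone_metrics(traj)
        assert z["thigmo_time"] == 0.0

    def test_diagonal_crossing_matches_per_frame_oracle(self):
        n = 900
        traj = make_traj(np.linspace(0.5, 49.5, n), np.linspace(0.5, 49.5, n))
        z = bh.zone_metrics(traj, 0.25, "linear")
        # brute-force per-frame classification
        band = 0.25 / 2 * 50.0
        inside = ((traj.x >= band) & (traj.x <= 50 - band)
                  & (traj.y >= band) & (traj.y <= 50 - band))
        assert z["center_time"] == pytest.approx(inside.sum() / FR)
        assert z["thigmo_time"] == pytest.approx((~inside).sum() / FR)

    def test_times_partition_session_duration(self):
        rng = np.random.default_rng(1)
        traj = make_traj(rng.uniform(0, 50, 500), rng.uniform(0, 50, 500))
        z = bh.zone_metrics(traj)
        assert z["center_time"] + z["thigmo_time"] == pytest.approx(
            traj.duration, abs=1e-9)

    def test_area_mode_widens_periphery(self):
        rng = np.random.default_rng(2)
        traj = make_traj(rng.uniform(0, 50, 2000), rng.uniform(0, 50, 2000))
        lin = bh.zone_metrics(traj, 0.25, "linear")
        area = bh.zone_metrics(traj, 0.25, "area")
        assert area["thigmo_time"] < lin["thigmo_time"]


def brute_force_focused(dips, max_gap=5.0):
    """Oracle: test every contiguous dip range for validity and maximality."""
    dips = sorted(dips)
    n = len(dips)

    def valid(i, j):  # dips i..j chain with all gaps <= max_gap
        return all(dips[k + 1][0] - dips[k][1] <= max_gap for k in range(i, j))

    episodes, isolated = [], []
    for i in range(n):
        for j in range(i, n):
            if not valid(i, j):
                continue
            left_ok = i == 0 or not valid(i - 1, j)
            right_ok = j == n - 1 or not valid(i, j + 1)
            if left_ok and right_ok:
                if j > i:
                    episodes.append((dips[i][0], dips[j][1]))
                else:
                    isolated.append(dips[i])
    return episodes, isolated


class TestFocusedExploration:
    def test_two_dips_within_five_seconds_chain(self):
        # a dip ending at 0 s and one starting at 3 s form one episode
        episodes, isolated = bh.detect_focused_exploration(
            dip_table([(0.0, 0.0), (3.0, 4.0)]))
        assert episodes == [(0.0, 4.0)]
        assert isolated == []

    def test_dips_six_seconds_apart_stay_isolated(self):
        episodes, isolated = bh.detect_focused_exploration(
            dip_table([(0.0, 1.0), (7.0, 8.0)]))
        assert episodes == []
        assert len(isolated) == 2

    def test_transitive_chaining_spans_all_dips(self):
        # gaps of 4 s merge transitively even though first-to-last exceeds 5 s
        episodes, isolated = bh.detect_focused_exploration(
            dip_table([(0.0, 0.5), (4.5, 5.0), (9.0, 9.5)]))
        assert episodes == [(0.0, 9.5)]
        assert isolated == []

    def test_every_dip_in_exactly_one_category(self, rng):
        starts = np.sort(rng.uniform(0, 100, 12))
        pairs = [(s, s + 0.5) for s in starts]
        episodes, isolated = bh.detect_focused_exploration(dip_table(pairs))
        covered = sum(1 for s, e in pairs
                      if any(a <= s and e <= b for a, b in episodes))
        assert covered + len(isolated) == len(pairs)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        starts = np.sort(rng.uniform(0, 60, n))
        durs = rng.uniform(0.1, 2.0, n)
        pairs = []
        t = 0.0
        for s, d in zip(starts, durs):  # enforce non-overlap
            a = max(s, t)
            pairs.append((a, a + d))
            t = a + d
        got = bh.detect_focused_exploration(dip_table(pairs))
        assert got == brute_force_focused(pairs)


class TestEthogram:
    def test_manual_rearing_overrides_motion(self):
        n = int(10 * FR)
        traj = make_traj(1 + 10.0 / FR * np.arange(n), np.full(n, 25.0),
                         motion=np.full(n, 8.0), arena=(120.0, 50.0))
        manual = EventTable(pd.DataFrame(
            [{"behavior": "rearing", "start": 2.0, "stop": 4.0}]))
        etho = bh.build_ethogram(traj, manual)
        assert etho.duration_of("rearing") == pytest.approx(2.0, abs=0.1)
        assert etho.duration_of("locomotion") == pytest.approx(8.0, abs=0.2)

    def test_still_session_is_immobility(self):
        n = 60
        traj = make_traj(np.full(n, 25.0), np.full(n, 25.0),
                         motion=np.full(n, 0.2))
        etho = bh.build_ethogram(traj)
        assert etho.duration_of("immobility") == pytest.approx(n / FR)

    def test_sixteen_frame_still_session_below_bout_rule_is_surveying(self):
        traj = make_traj(np.full(15, 25.0), np.full(15, 25.0),
                         motion=np.full(15, 0.2))
        etho = bh.build_ethogram(traj)
        assert etho.duration_of("surveying") == pytest.approx(15 / FR)

    def test_empty_trajectory_errors(self):
        with pytest.raises(DataError):
            make_traj([], [])

    def test_time_translation_invariance(self):
        n = int(20 * FR)
        x = np.concatenate([np.full(n // 2, 25.0),
                            25.0 + 10.0 / FR * np.arange(n - n // 2)])
        traj = make_traj(x, np.full(n, 25.0), arena=(140.0, 50.0))
        shifted = bh.Trajectory(
            frame=traj.frame, time=traj.time + 1000.0, x=traj.x, y=traj.y,
            motion=traj.motion, frame_rate=FR, arena=traj.arena)
        b0 = bh.detect_immobility(traj)
        b1 = bh.detect_immobility(shifted)
        assert np.allclose(np.asarray(b1) - 1000.0, np.asarray(b0))


class TestEpochMetrics:
    def make_session(self):
        script = []
        for _ in range(5):  # one scripted cycle per 60-s epoch
            script += [synthetic.BoutSpec("immobility", 30.0),
                       synthetic.BoutSpec("locomotion", 30.0, 10.0)]
        traj, _ = synthetic.gen_tracking(script=script, seed=0)
        return traj

    def test_identical_epochs_normalize_to_zero(self):
        traj = self.make_session()
        etho = bh.build_ethogram(traj)
        m = bh.epoch_metrics(etho, traj, design=("Pre", "ON", "OFF", "ON", "OFF"),
                             epoch_length=60.0)
        # behavior repeats exactly each epoch, so Pre-corrected values vanish
        assert np.allclose(m.normalized_to_pre.to_numpy(), 0.0, atol=0.6)

    def test_dips_only_in_on_epochs(self):
        traj = self.make_session()
        etho = bh.build_ethogram(traj)
        dips = dip_table([(70.0, 71.0), (80.0, 81.0), (190.0, 191.0)])
        m = bh.epoch_metrics(etho, traj, dips,
                             design=("Pre", "ON", "OFF", "ON", "OFF"),
                             epoch_length=60.0)
        assert m.averaged.loc["Pre", "head_dip_count"] == 0
        assert m.normalized_to_pre.loc["ON", "head_dip_count"] == pytest.approx(1.5)

    def test_design_past_session_end_errors(self):
        traj = self.make_session()
        etho = bh.build_ethogram(traj)
        with pytest.raises(ParameterError):
            bh.epoch_metrics(etho, traj, design=("Pre", "ON"), epoch_length=300.0)
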