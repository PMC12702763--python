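"""Trial-level test scoring: SSRT integration method, difference scores,
tracking closeness, span scores, and the long-format trial reducer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from takeoverpls.errors import ValidationError
from takeoverpls.scoring import (
    StopSignalRecord,
    TrackingRecord,
    TwoConditionRecord,
    difference_score,
    mean_score,
    percent_time_close,
    score_trials,
    span_score,
    ssrt_integration,
)

GO_RTS = (300.0, 320.0, 340.0, 360.0, 380.0, 400.0, 420.0, 440.0, 460.0, 500.0)


def stop_trials(n_respond, n_inhibit, ssd):
    return tuple([(ssd, True)] * n_respond + [(ssd, False)] * n_inhibit)


class TestSSRT:
    def test_hand_ranked_example(self):
        # p = 0.5 over 10 go trials -> 5th RT = 380; SSRT = 380 - 180 = 200
        rec = StopSignalRecord(GO_RTS, stop_trials(5, 5, 180.0))
        assert ssrt_integration(rec) == 200.0

    def test_always_responding_gives_max_go_rt(self):
        rec = StopSignalRecord(GO_RTS, stop_trials(4, 0, 0.0))
        assert ssrt_integration(rec) == max(GO_RTS)

    def test_omission_replaced_by_max_go_rt(self):
        # [300, 350, 400] + one omission -> [300, 350, 400, 400];
        # p = 0.5 -> n = 2 -> 350; SSRT = 350 - 100 = 250
        rec = StopSignalRecord((300.0, 350.0, 400.0, None),
                               stop_trials(2, 2, 100.0))
        assert ssrt_integration(rec) == 250.0

    def test_never_responding_is_undefined(self):
        rec = StopSignalRecord(GO_RTS, stop_trials(0, 5, 150.0))
        with pytest.raises(ValidationError, match="p = 0"):
            ssrt_integration(rec)

    def test_all_go_omitted_is_undefined(self):
        rec = StopSignalRecord((None, None), stop_trials(1, 1, 150.0))
        with pytest.raises(ValidationError):
            ssrt_integration(rec)

    @given(st.permutations(list(GO_RTS)))
    def test_invariant_to_go_rt_order(self, shuffled):
        baseline = ssrt_integration(
            StopSignalRecord(GO_RTS, stop_trials(3, 7, 120.0)))
        permuted = ssrt_integration(
            StopSignalRecord(tuple(shuffled), stop_trials(3, 7, 120.0)))
        assert permuted == baseline

    @given(st.integers(1, 10), st.floats(0.0, 400.0))
    def test_monotone_in_p_and_antitone_in_ssd(self, n_respond, ssd):
        rec = StopSignalRecord(GO_RTS, stop_trials(n_respond, 10 - n_respond, ssd))
        val = ssrt_integration(rec)
        # increasing the mean SSD decreases SSRT one-for-one
        rec_hi = StopSignalRecord(GO_RTS,
                                  stop_trials(n_respond, 10 - n_respond, ssd + 50))
        assert ssrt_integration(rec_hi) == pytest.approx(val - 50)
        # increasing p (more responses on stop trials) never lowers the quantile
        if n_respond < 10:
            rec_p = StopSignalRecord(GO_RTS,
                                     stop_trials(n_respond + 1, 9 - n_respond, ssd))
            assert ssrt_integration(rec_p) >= val


class TestDifferenceScore:
    @pytest.mark.parametrize("hard,easy,expected", [
        (900.0, 600.0, 300.0),   # 3-back minus 1-back mean RT
        (5.0, 5.0, 0.0),
        (75.0, 30.0, 45.0),      # TMT-B minus TMT-A
    ])
    def test_hard_minus_easy(self, hard, easy, expected):
        assert difference_score(TwoConditionRecord(hard, easy)) == expected

    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_antisymmetric_under_condition_swap(self, hard, easy):
        rec = TwoConditionRecord(hard, easy)
        assert difference_score(rec.swapped()) == -difference_score(rec)


class TestTracking:
    def test_boundary_counts_as_close(self):
        rec = TrackingRecord((0.2, 0.5, 0.7, 1.0), threshold=0.5)
        assert percent_time_close(rec) == 50.0

    def test_all_close_and_none_close(self):
        assert percent_time_close(TrackingRecord((0.0, 0.0))) == 100.0
        assert percent_time_close(TrackingRecord((0.6, 2.0))) == 0.0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValidationError):
            percent_time_close(TrackingRecord(()))

    @given(st.lists(st.floats(0, 5), min_size=1, max_size=40),
           st.floats(0.01, 2.0))
    def test_bounded_between_0_and_100(self, distances, threshold):
        val = percent_time_close(TrackingRecord(tuple(distances), threshold))
        assert 0.0 <= val <= 100.0


class TestSpanScore:
    @pytest.mark.parametrize("levels,expected", [
        ([(3, True), (4, True), (5, True), (6, False), (6, False)], 5),
        ([(2, False), (2, False)], 0),
        ([(2, True)], 2),
    ])
    def test_highest_level_passed(self, levels, expected):
        assert span_score(levels) == expected


def test_mean_score_is_plain_mean():
    assert mean_score([10.0, 20.0, 30.0]) == 20.0


class TestScoreTrials:
    def test_long_format_reduces_to_catalogue_columns(self):
        rows = []
        # stop-signal: 4 go trials (one omitted), 2 stop trials (1 responded)
        rows += [("p1", "stop_signal", "go_rt", v) for v in (300, 350, 400)]
        rows += [("p1", "stop_signal", "go_omitted", 0)]
        rows += [("p1", "stop_signal", "stop_respond", 100),
                 ("p1", "stop_signal", "stop_inhibit", 100)]
        rows += [("p1", "visuomanual_coordination", "distance", d)
                 for d in (0.2, 0.5, 0.7, 1.0)]
        rows += [("p1", "multiple_object_avoidance", "time_to_collision", t)
                 for t in (30.0, 50.0)]
        rows += [("p1", "multiple_object_tracking", "speed_threshold", 1.4)]
        rows += [("p1", "corsi", "level_pass", 4), ("p1", "corsi", "level_fail", 5),
                 ("p1", "corsi", "level_pass", 5), ("p1", "corsi", "level_fail", 6),
                 ("p1", "corsi", "level_fail", 6)]
        rows += [("p1", "trail_making", "time_a", 30.0),
                 ("p1", "trail_making", "time_b", 75.0)]
        rows += [("p1", "n_back", "rt_1back", 600), ("p1", "n_back", "rt_3back", 900),
                 ("p1", "n_back", "correct_1back", 1),
                 ("p1", "n_back", "correct_3back", 0)]
        rows += [("p1", "flanker", "rt_congruent", 400),
                 ("p1", "flanker", "rt_incongruent", 470),
                 ("p1", "flanker", "correct", 1), ("p1", "flanker", "correct", 0)]
        rows += [("p1", "tower_of_london", "solved", 1),
                 ("p1", "tower_of_london", "solved", 0),
                 ("p1", "tower_of_london", "extra_moves", 2)]
        trials = pd.DataFrame(rows, columns=["participant", "task", "measure", "value"])
        scored = score_trials(trials)
        row = scored.loc["p1"]
        assert row["ssrt"] == 250.0           # hand example above
        assert row["vmc_time_close"] == 50.0
        assert row["moa_mean_time"] == 40.0
        assert row["mot_speed"] == 1.4
        assert row["corsi_span"] == 5
        assert row["tmt_b_minus_a"] == 45.0
        assert row["nback_rt_diff"] == 300.0
        assert row["nback_accuracy_diff"] == -100.0
        assert row["flanker_rt_diff"] == 70.0
        assert row["flanker_accuracy"] == 50.0
        assert row["tol_n_solved"] == 1
        assert row["tol_extra_moves"] == 2

    def test_unknown_task_rejected(self):
        trials = pd.DataFrame(
            [("p1", "mystery", "x", 1.0)],
            columns=["participant", "task", "measure", "value"],
        )
        with pytest.raises(ValidationError, match="mystery"):
            score_trials(trials)
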