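"""Predictor-level scores from trial-level cognitive / visuo-attentional records.

Each test of the battery reduces to one or two numbers per participant:

* stop-signal task -> SSRT by the integration method,
* two-condition tasks (N-back, Flanker, Trail Making) -> hard-minus-easy
  difference of a summary statistic,
* visuomanual coordination -> percent of time within a closeness threshold
  of the moving target,
* Corsi block tapping -> highest level passed,
* multiple object avoidance -> mean time to collision over trials,
* multiple object tracking -> an externally computed speed threshold that is
  validated and passed through,
* Tower of London -> number of models solved and superfluous moves.

:func:`score_trials` maps a long-format trial table (one row per trial, see
its docstring) onto one predictor-level row per participant, compatible with
the abilities-matrix column names of the default catalogue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "StopSignalRecord", "TwoConditionRecord", "TrackingRecord",
    "ssrt_integration", "difference_score", "percent_time_close",
    "span_score", "mean_score", "tracking_speed_threshold", "score_trials",
]


@dataclass(frozen=True)
class StopSignalRecord:
    """Trial-level stop-signal data for one participant.

    ``go_rts`` holds one entry per go trial: the reaction time in ms, or
    ``None`` for an omitted response.  ``stop_trials`` holds one
    ``(stop_signal_delay_ms, responded)`` pair per stop trial.
    """

    go_rts: tuple[float | None, ...]
    stop_trials: tuple[tuple[float, bool], ...]

    def __post_init__(self) -> None:
        if not self.go_rts:
            raise ValidationError("stop-signal record needs at least one go trial")
        if not self.stop_trials:
            raise ValidationError("stop-signal record needs at least one stop trial")
        for rt in self.go_rts:
            if rt is not None and (not math.isfinite(rt) or rt < 0):
                raise ValidationError(f"invalid go RT: {rt!r}")
        for ssd, _responded in self.stop_trials:
            if not math.isfinite(ssd) or ssd < 0:
                raise ValidationError(f"invalid stop-signal delay: {ssd!r}")
        object.__setattr__(self, "go_rts", tuple(self.go_rts))
        object.__setattr__(
            self, "stop_trials",
            tuple((float(s), bool(r)) for s, r in self.stop_trials),
        )

    @property
    def p_respond(self) -> float:
        """Probability of (incorrectly) responding on stop trials."""
        responded = sum(1 for _ssd, r in self.stop_trials if r)
        return responded / len(self.stop_trials)

    @property
    def mean_ssd(self) -> float:
        return float(np.mean([ssd for ssd, _r in self.stop_trials]))


def ssrt_integration(record: StopSignalRecord) -> float:
    """Stop-signal reaction time (ms) by the integration method.

    Go RTs are ranked ascending with omitted go responses replaced by the
    maximum observed go RT; the n-th RT is taken, where
    ``n = ceil(p * n_go)`` and ``p`` is the probability of responding on stop
    trials; SSRT is that RT minus the mean stop-signal delay.
    """
    p = record.p_respond
    if p == 0:
        raise ValidationError(
            "SSRT undefined: participant never responded on stop trials (p = 0)"
        )
    observed = [rt for rt in record.go_rts if rt is not None]
    if not observed:
        raise ValidationError("SSRT undefined: no observed go reaction times")
    max_rt = max(observed)
    rts = sorted((rt if rt is not None else max_rt) for rt in record.go_rts)
    n = math.ceil(p * len(rts))
    n = min(max(n, 1), len(rts))
    return float(rts[n - 1] - record.mean_ssd)


@dataclass(frozen=True)
class TwoConditionRecord:
    """Summary statistic of a hard condition and of an easy/calibration one."""

    hard: float
    easy: float
    hard_label: str = "hard"
    easy_label: str = "easy"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.hard) and math.isfinite(self.easy)):
            raise ValidationError("condition statistics must be finite")

    def swapped(self) -> "TwoConditionRecord":
        return TwoConditionRecord(self.easy, self.hard, self.easy_label, self.hard_label)


def difference_score(record: TwoConditionRecord) -> float:
    """Hard-condition statistic minus easy/calibration-condition statistic."""
    return record.hard - record.easy


@dataclass(frozen=True)
class TrackingRecord:
    """Per-sample cursor-to-target distances (cm) with a closeness threshold."""

    distances: tuple[float, ...]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("closeness threshold must be positive")
        for d in self.distances:
            if not math.isfinite(d) or d < 0:
                raise ValidationError(f"invalid distance sample: {d!r}")
        object.__setattr__(self, "distances", tuple(float(d) for d in self.distances))


def percent_time_close(record: TrackingRecord) -> float:
    """Percent of samples at distance <= threshold (boundary counts as close)."""
    if not record.distances:
        raise ValidationError("tracking record has no samples")
    close = sum(1 for d in record.distances if d <= record.threshold)
    return 100.0 * close / len(record.distances)


def span_score(levels: Sequence[tuple[int, bool]]) -> int:
    """Highest level with at least one pass (0 if none was passed).

    ``levels`` is a sequence of ``(level, passed)`` pairs in administration
    order; the two-consecutive-failures termination rule is assumed to have
    been applied when the task was run.
    """
    passed = [int(level) for level, ok in levels if ok]
    return max(passed) if passed else 0


def mean_score(values: Sequence[float]) -> float:
    """Plain arithmetic mean over trials (e.g. mean time to collision)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValidationError("mean score needs a non-empty finite sample")
    return float(arr.mean())


def tracking_speed_threshold(value: float) -> float:
    """Validate and pass through the externally computed MOT speed threshold."""
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"invalid tracking speed threshold: {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# Long-format trial table -> predictor-level rows
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("participant", "task", "measure", "value")


def _two_condition(sub: pd.DataFrame, hard: str, easy: str) -> float:
    means = sub.groupby("measure")["value"].mean()
    for key in (hard, easy):
        if key not in means:
            raise ValidationError(f"missing measure {key!r} for two-condition score")
    return difference_score(TwoConditionRecord(means[hard], means[easy], hard, easy))


def score_trials(trials: pd.DataFrame, closeness_threshold: float = 0.5) -> pd.DataFrame:
    """Reduce a long-format trial table to one predictor row per participant.

    ``trials`` must have columns ``participant, task, measure, value`` with
    one row per trial-level observation:

    ==========================  ======================  =============================
    task                        measure                 value
    ==========================  ======================  =============================
    stop_signal                 go_rt                   go RT in ms
    stop_signal                 go_omitted              ignored (flags an omission)
    stop_signal                 stop_respond            SSD in ms (response made)
    stop_signal                 stop_inhibit            SSD in ms (inhibited)
    visuomanual_coordination    distance                cursor-target distance in cm
    multiple_object_avoidance   time_to_collision       seconds, one row per trial
    multiple_object_tracking    speed_threshold         precomputed threshold (a.u.)
    n_back                      rt_1back / rt_3back     RT in ms
    n_back                      correct_1back/_3back    0/1
    flanker                     rt_congruent/_incongr.  RT in ms ("rt_incongruent")
    flanker                     correct                 0/1
    corsi                       level_pass/level_fail   level attempted
    trail_making                time_a / time_b         board completion time in s
    tower_of_london             solved                  0/1, one row per model
    tower_of_london             extra_moves             superfluous moves (solved)
    ==========================  ======================  =============================

    Returns a wide DataFrame indexed by participant whose columns use the
    default-catalogue predictor names; tasks absent from the table simply
    yield no column.
    """
    for col in _REQUIRED_COLUMNS:
        if col not in trials.columns:
            raise ValidationError(f"trial table lacks required column {col!r}")
    rows: dict[str, dict[str, float]] = {}
    for (pid, task), sub in trials.groupby(["participant", "task"], sort=True):
        out = rows.setdefault(str(pid), {})
        if task == "stop_signal":
            go = [
                (float(v) if m == "go_rt" else None)
                for m, v in zip(sub["measure"], sub["value"])
                if m in ("go_rt", "go_omitted")
            ]
            stops = [
                (float(v), m == "stop_respond")
                for m, v in zip(sub["measure"], sub["value"])
                if m in ("stop_respond", "stop_inhibit")
            ]
            out["ssrt"] = ssrt_integration(StopSignalRecord(tuple(go), tuple(stops)))
        elif task == "visuomanual_coordination":
            d = sub.loc[sub["measure"] == "distance", "value"].astype(float)
            out["vmc_time_close"] = percent_time_close(
                TrackingRecord(tuple(d), closeness_threshold)
            )
        elif task == "multiple_object_avoidance":
            t = sub.loc[sub["measure"] == "time_to_collision", "value"].astype(float)
            out["moa_mean_time"] = mean_score(tuple(t))
        elif task == "multiple_object_tracking":
            v = sub.loc[sub["measure"] == "speed_threshold", "value"].astype(float)
            if len(v) != 1:
                raise ValidationError(
                    f"participant {pid!r}: expected exactly one speed_threshold"
                )
            out["mot_speed"] = tracking_speed_threshold(float(v.iloc[0]))
        elif task == "n_back":
            out["nback_rt_diff"] = _two_condition(sub, "rt_3back", "rt_1back")
            acc = _two_condition(sub, "correct_3back", "correct_1back")
            out["nback_accuracy_diff"] = 100.0 * acc
        elif task == "flanker":
            out["flanker_rt_diff"] = _two_condition(sub, "rt_incongruent", "rt_congruent")
            correct = sub.loc[sub["measure"] == "correct", "value"].astype(float)
            if correct.empty:
                raise ValidationError(f"participant {pid!r}: no flanker 'correct' rows")
            out["flanker_accuracy"] = 100.0 * float(correct.mean())
        elif task == "corsi":
            levels = [
                (int(v), m == "level_pass")
                for m, v in zip(sub["measure"], sub["value"])
                if m in ("level_pass", "level_fail")
            ]
            out["corsi_span"] = span_score(levels)
        elif task == "trail_making":
            out["tmt_b_minus_a"] = _two_condition(sub, "time_b", "time_a")
        elif task == "tower_of_london":
            solved = sub.loc[sub["measure"] == "solved", "value"].astype(float)
            extra = sub.loc[sub["measure"] == "extra_moves", "value"].astype(float)
            out["tol_n_solved"] = float(solved.sum())
            out["tol_extra_moves"] = float(extra.sum())
        else:
            raise ValidationError(f"unknown task {task!r} in trial table")
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
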